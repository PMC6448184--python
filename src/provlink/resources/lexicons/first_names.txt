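Aaron
Abigail
Adam
Adrian
Alan
Albert
Alexander
Alexandra
Alice
Alicia
Allison
Amanda
Amber
Amelia
Amy
Andrea
Andrew
Angela
Anita
Ann
Anna
Anthony
April
Arthur
Ashley
Audrey
Austin
Barbara
Beatrice
Benjamin
Bernard
Beth
Beverly
Bonnie
Bradley
Brandon
Brenda
Brian
Bridget
Brittany
Bruce
Bryan
Caitlin
Caleb
Cameron
Carl
Carla
Carmen
Carol
Caroline
Carolyn
Catherine
Cecilia
Charles
Charlotte
Cheryl
Christian
Christina
Christine
Christopher
Cindy
Claire
Clara
Clifford
Colin
Colleen
Connie
Constance
Corey
Courtney
Craig
Crystal
Cynthia
Dale
Daniel
Danielle
Darlene
David
Dawn
Deborah
Denise
Dennis
Derek
Diana
Diane
Dominic
Donald
Donna
Doris
Dorothy
Douglas
Duane
Dustin
Dylan
Edith
Edmund
Edward
Eileen
Elaine
Eleanor
Elena
Elizabeth
Ellen
Emily
Emma
Eric
Erica
Erin
Ernest
Esther
Ethan
Eugene
Evelyn
Felicia
Fiona
Frances
Francis
Frank
Frederick
Gabriel
Gail
Gary
Geoffrey
George
Gerald
Gina
Glenn
Gloria
Gordon
Grace
Gregory
Gretchen
Hannah
Harold
Harriet
Harry
Heather
Helen
Henry
Herbert
Holly
Howard
Hugh
Ian
Irene
Isaac
Isabel
Jacob
Jacqueline
James
Jane
Janet
Janice
Jared
Jason
Jeffrey
Jennifer
Jeremy
Jerome
Jessica
Joan
Joanne
Jocelyn
John
Jonathan
Jordan
Joseph
Josephine
Joshua
Joyce
Judith
Julia
Julian
Julie
Justin
Karen
Katherine
Kathleen
Kathryn
Keith
Kelly
Kenneth
Kevin
Kimberly
Kristen
Kurt
Kyle
Laura
Lauren
Laurence
Leah
Leonard
Leslie
Lillian
Linda
Lindsay
Lisa
Lloyd
Lois
Louis
Louise
Lucas
Lucille
Lydia
Lynn
Madeline
Malcolm
Marcia
Margaret
Maria
Marianne
Marilyn
Marion
Marjorie
Mark
Martha
Martin
Marvin
Mary
Matthew
Maureen
Maxwell
Megan
Melanie
Melissa
Meredith
Michael
Michelle
Mildred
Miriam
Mitchell
Molly
Monica
Morgan
Nancy
Naomi
Natalie
Nathan
Nathaniel
Neil
Nicholas
Nicole
Nina
Noah
Nora
Norman
Olivia
Oscar
Pamela
Patricia
Patrick
Paul
Paula
Pauline
Peter
Philip
Phyllis
Priscilla
Rachel
Ralph
Randall
Raymond
Rebecca
Regina
Renee
Rhonda
Richard
Rita
Robert
Roberta
Rodney
Roger
Ronald
Rosalind
Rose
Rosemary
Ross
Roy
Russell
Ruth
Ryan
Sabrina
Samantha
Samuel
Sandra
Sarah
Scott
Sean
Sharon
Sheila
Shirley
Sidney
Simon
Sophia
Spencer
Stacy
Stanley
Stephanie
Stephen
Steven
Stuart
Susan
Suzanne
Sylvia
Tamara
Teresa
Terrence
Theodore
Theresa
Thomas
Timothy
Tracy
Travis
Trevor
Tyler
Valerie
Vanessa
Veronica
Victor
Victoria
Vincent
Violet
Virginia
Vivian
Walter
Wanda
Warren
Wayne
Wendy
Wesley
William
Winifred
Yvonne
Zachary
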