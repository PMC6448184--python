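Abbott
Acevedo
Acosta
Adams
Aguilar
Alexander
Allen
Alvarez
Anderson
Andrews
Armstrong
Arnold
Atkinson
Austin
Bailey
Baker
Baldwin
Ballard
Banks
Barber
Barker
Barnes
Barrett
Barton
Bates
Bauer
Baxter
Becker
Bell
Bennett
Benson
Bentley
Berger
Bishop
Black
Blackwell
Blair
Blake
Bowen
Bowman
Boyd
Bradley
Brady
Brennan
Brewer
Bridges
Briggs
Brooks
Brown
Bryant
Buchanan
Burgess
Burke
Burns
Burton
Bush
Butler
Byrd
Caldwell
Calhoun
Callahan
Cameron
Campbell
Cannon
Cardenas
Carey
Carlson
Carpenter
Carroll
Carter
Castillo
Chambers
Chandler
Chapman
Chavez
Chen
Christensen
Clark
Clarke
Clayton
Cline
Cobb
Cohen
Cole
Coleman
Collier
Collins
Compton
Conley
Conner
Conrad
Contreras
Conway
Cook
Cooper
Copeland
Cortez
Costa
Coughlin
Cowan
Cox
Craig
Crawford
Crosby
Cross
Cruz
Cummings
Cunningham
Curtis
Dalton
Daniels
Daugherty
Davenport
Davidson
Davis
Dawson
Decker
Delacruz
Delaney
Delgado
Dennis
Diaz
Dickerson
Dickson
Dillon
Dixon
Dodson
Dominguez
Donaldson
Donovan
Dorsey
Dougherty
Douglas
Doyle
Drake
Dudley
Duffy
Duncan
Dunlap
Dunn
Duran
Durham
Dyer
Eaton
Edwards
Elliott
Ellis
Emerson
English
Erickson
Espinoza
Estes
Estrada
Evans
Everett
Farley
Farmer
Farrell
Faulkner
Ferguson
Fernandez
Fields
Figueroa
Finley
Fischer
Fisher
Fitzgerald
Fitzpatrick
Fleming
Fletcher
Flores
Flowers
Floyd
Flynn
Foley
Forbes
Ford
Foster
Fowler
Fox
Franco
Frank
Franklin
Frazier
Freeman
French
Frost
Fuentes
Fuller
Gallagher
Gallegos
Galloway
Gamble
Garcia
Gardner
Garner
Garrett
Garrison
Garza
Gates
Gentry
George
Gibbs
Gibson
Gilbert
Giles
Gill
Gillespie
Gilmore
Glass
Glenn
Glover
Goldberg
Golden
Gomez
Gonzalez
Goodman
Goodwin
Gordon
Gould
Graham
Grant
Graves
Gray
Green
Greene
Greer
Gregory
Griffin
Griffith
Grimes
Gross
Guerra
Guerrero
Guthrie
Gutierrez
Guzman
Hahn
Hale
Haley
Hall
Hamilton
Hammond
Hampton
Hancock
Haney
Hansen
Hanson
Hardin
Harding
Hardy
Harmon
Harper
Harrell
Harrington
Harris
Harrison
Hart
Hartman
Harvey
Hatfield
Hawkins
Hayden
Hayes
Haynes
Heath
Hebert
Henderson
Hendricks
Henry
Hensley
Herman
Hernandez
Herrera
Herring
Hess
Hester
Hickman
Hicks
Higgins
Hill
Hines
Hinton
Hobbs
Hodges
Hoffman
Hogan
Holcomb
Holden
Holland
Holloway
Holmes
Holt
Hood
Hoover
Hopkins
Horn
Horton
House
Houston
Howard
Howell
Hubbard
Huber
Hudson
Huff
Huffman
Hughes
Hull
Humphrey
Hunt
Hunter
Hurley
Hurst
Hutchinson
Ingram
Irwin
Jackson
Jacobs
Jacobson
James
Jarvis
Jefferson
Jenkins
Jennings
Jensen
Jimenez
Johns
Johnson
Johnston
Jones
Jordan
Joseph
Joyce
Juarez
Kane
Kaufman
Keller
Kelley
Kelly
Kemp
Kennedy
Kent
Kerr
Kim
King
Kirby
Kirk
Klein
Knapp
Knight
Knox
Koch
Kramer
Krueger
Lamb
Lambert
Lancaster
Landry
Lane
Lang
Langley
Lara
Larsen
Larson
Lawrence
Lawson
Leach
Leblanc
Lee
Leon
Leonard
Lester
Levine
Levy
Lewis
Lindsey
Little
Livingston
Lloyd
Logan
Long
Lopez
Lowe
Lowery
Lucas
Luna
Lynch
Lyons
Macdonald
Macias
Mack
Madden
Maddox
Mahoney
Maldonado
Malone
Mann
Manning
Marks
Marquez
Marsh
Marshall
Martin
Martinez
Mason
Massey
Mathews
Mathis
Matthews
Maxwell
May
Mayer
Maynard
Mayo
Mays
Mcbride
Mccall
Mccarthy
Mcclain
Mcclure
Mcconnell
Mccormick
Mccoy
Mccullough
Mcdaniel
Mcdonald
Mcdowell
Mcfarland
Mcgee
Mcguire
Mcintosh
Mcintyre
Mckay
Mckee
Mckenzie
Mckinney
Mclaughlin
Mclean
Mcmahon
Mcmillan
Mcneil
Mcpherson
Meadows
Medina
Mejia
Melendez
Melton
Mendez
Mendoza
Mercado
Mercer
Merrill
Merritt
Meyer
Meyers
Michael
Middleton
Miles
Miller
Mills
Miranda
Mitchell
Molina
Monroe
Montgomery
Montoya
Moody
Moon
Mooney
Moore
Morales
Moran
Moreno
Morgan
Morris
Morrison
Morrow
Morse
Morton
Moses
Mosley
Moss
Mueller
Mullen
Mullins
Munoz
Murphy
Murray
Myers
Nash
Navarro
Neal
Nelson
Newman
Newton
Nguyen
Nichols
Nicholson
Nielsen
Nixon
Noble
Nolan
Norman
Norris
Norton
Nunez
Obrien
Ochoa
Oconnor
Odom
Odonnell
Oliver
Olsen
Olson
Oneal
Oneil
Orozco
Orr
Ortega
Ortiz
Osborn
Osborne
Owen
Owens
Pace
Pacheco
Padilla
Page
Palmer
Park
Parker
Parks
Parrish
Parsons
Patel
Patrick
Patterson
Patton
Paul
Payne
Pearson
Peck
Pena
Pennington
Perez
Perkins
Perry
Person
Peters
Petersen
Peterson
Petty
Phelps
Phillips
Pickett
Pierce
Pittman
Pitts
Pollard
Poole
Pope
Porter
Potter
Potts
Powell
Powers
Pratt
Preston
Price
Prince
Pruitt
Pugh
Quinn
Ramirez
Ramos
Ramsey
Randall
Randolph
Rasmussen
Ratliff
Ray
Raymond
Reed
Reese
Reeves
Reid
Reilly
Reyes
Reynolds
Rhodes
Rice
Rich
Richard
Richards
Richardson
Richmond
Riddle
Riggs
Riley
Rios
Rivas
Rivera
Rivers
Roach
Robbins
Roberson
Roberts
Robertson
Robinson
Robles
Rocha
Rodgers
Rodriguez
Rogers
Rojas
Rollins
Roman
Romero
Rosa
Rosales
Rosario
Rose
Ross
Roth
Rowe
Rowland
Roy
Rubio
Ruiz
Rush
Russell
Russo
Rutledge
Ryan
Salas
Salazar
Salinas
Sampson
Sanchez
Sanders
Sandoval
Sanford
Santana
Santiago
Santos
Sargent
Saunders
Savage
Sawyer
Schmidt
Schneider
Schroeder
Schultz
Schwartz
Scott
Sellers
Serrano
Sexton
Shaffer
Shannon
Sharp
Shaw
Shelton
Shepard
Shepherd
Sheppard
Sherman
Shields
Short
Silva
Simmons
Simon
Simpson
Sims
Singleton
Skinner
Slater
Sloan
Small
Smith
Snider
Snow
Snyder
Solis
Solomon
Sosa
Soto
Sparks
Spears
Spence
Spencer
Stafford
Stanley
Stanton
Stark
Steele
Stein
Stephens
Stephenson
Stevens
Stevenson
Stewart
Stokes
Stone
Stout
Strickland
Strong
Stuart
Suarez
Sullivan
Summers
Sutton
Swanson
Sweeney
Sweet
Sykes
Talley
Tanner
Tate
Taylor
Terrell
Terry
Thomas
Thompson
Thornton
Todd
Torres
Townsend
Tran
Travis
Trevino
Trujillo
Tucker
Turner
Tyler
Tyson
Underwood
Valdez
Valencia
Valentine
Valenzuela
Vance
Vargas
Vasquez
Vaughan
Vaughn
Vazquez
Vega
Velasquez
Velazquez
Velez
Villarreal
Vincent
Vinson
Wade
Wagner
Walker
Wall
Wallace
Waller
Walls
Walsh
Walter
Walters
Walton
Wang
Ward
Ware
Warner
Warren
Washington
Waters
Watkins
Watson
Watts
Weaver
Webb
Weber
Webster
Weeks
Weiss
Welch
Wells
West
Wheeler
Whitaker
White
Whitehead
Whitfield
Whitley
Whitney
Wiggins
Wilcox
Wilder
Wiley
Wilkerson
Wilkins
Wilkinson
William
Williams
Williamson
Willis
Wilson
Winters
Wise
Witt
Wolf
Wolfe
Wong
Wood
Woodard
Woods
Woodward
Wooten
Workman
Wright
Wyatt
Yang
Yates
York
Young
Zamora
Zavala
Zimmerman
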