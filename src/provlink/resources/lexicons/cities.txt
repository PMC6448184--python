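Hartford
New Haven
Stamford
Bridgeport
Waterbury
Norwalk
Danbury
New Britain
Bristol
Meriden
Milford
West Hartford
Middletown
Norwich
Shelton
Torrington
Trumbull
Glastonbury
Naugatuck
Newington
Cheshire
Vernon
Windsor
New London
Branford
New Milford
Westport
Wethersfield
Guilford
Stratford
Manchester
Enfield
Southington
Groton
Hamden
Fairfield
Wallingford
Farmington
Simsbury
Avon
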