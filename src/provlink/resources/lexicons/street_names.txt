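Park
High
Main
Oak
Maple
Cedar
Pine
Elm
Washington
Lake
Hill
Walnut
Spring
North
South
Ridge
Church
Willow
Mill
Sunset
Railroad
Jackson
Highland
Forest
River
Meadow
Franklin
Chestnut
Collins
Birch
Spruce
Hickory
Dogwood
Magnolia
Laurel
Poplar
Sycamore
Juniper
Hemlock
Aspen
Locust
Cherry
Apple
Orchard
Garden
Valley
Brook
Creek
Pond
Bay
Harbor
Beach
Shore
Island
Prospect
Pleasant
Fairview
Grandview
Lincoln
Jefferson
Madison
Monroe
Adams
Hamilton
Grant
Sherman
Colonial
Heritage
Liberty
Union
Federal
Commerce
Market
Broad
Center
Division
Front
Water
Bridge
Canal
Tower
Windsor
Essex
Sussex
Kent
Norfolk
Suffolk
Hartford
Newbury
Salem
Dover
Bristol
Camden
Trenton
Warwick
Berkshire
Hampshire
Somerset
Devon
Cornwall
Avon
Thames
Severn
Clyde
Tweed
Sterling
Granite
Cobblestone
Stonewall
Fieldstone
Millstone
Ironwood
Redwood
Rosewood
Driftwood
Lakewood
Elmwood
Oakwood
Maplewood
Ridgewood
Greenwood
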