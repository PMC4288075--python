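name,count
smith,1006
johnson,810
williams,699
jones,621
brown,621
davis,480
miller,424
wilson,339
moore,312
taylor,311
anderson,311
thomas,311
jackson,310
white,279
harris,275
martin,273
thompson,269
garcia,254
martinez,234
robinson,233
clark,231
rodriguez,229
lewis,226
lee,220
walker,219
hall,200
allen,199
young,193
hernandez,192
king,190
wright,189
lopez,187
hill,187
scott,185
green,183
adams,174
baker,171
gonzalez,166
nelson,162
carter,162
mitchell,160
perez,155
roberts,153
turner,152
phillips,149
campbell,149
parker,146
evans,144
edwards,139
collins,135
stewart,135
sanchez,133
morris,132
rogers,131
reed,129
cook,127
morgan,126
bell,126
murphy,125
bailey,124
rivera,123
cooper,123
richardson,122
cox,121
howard,121
ward,120
torres,119
peterson,118
gray,117
ramirez,116
james,115
watson,115
brooks,114
kelly,113
sanders,112
price,111
bennett,111
wood,110
barnes,109
ross,109
henderson,108
coleman,107
jenkins,107
perry,106
powell,105
long,105
patterson,105
hughes,104
flores,104
washington,103
butler,103
simmons,102
foster,101
gonzales,101
bryant,100
alexander,98
russell,97
griffin,97
diaz,94
hayes,94
myers,94
ford,93
hamilton,93
graham,93
sullivan,93
wallace,92
woods,92
cole,91
west,91
owens,89
reynolds,89
fisher,89
ellis,88
harrison,88
gibson,87
mcdonald,87
cruz,86
marshall,86
ortiz,86
gomez,86
murray,85
freeman,85
wells,84
webb,83
simpson,82
stevens,82
tucker,82
porter,81
hunter,81
hicks,80
crawford,80
henry,79
boyd,79
mason,79
morales,78
kennedy,78
warren,78
dixon,77
ramos,77
reyes,76
burns,76
gordon,76
shaw,75
holmes,74
rice,73
robertson,73
hunt,72
black,72
daniels,72
palmer,72
mills,70
nichols,70
grant,70
knight,69
ferguson,69
rose,68
stone,68
hawkins,67
dunn,67
perkins,66
hudson,66
spencer,65
gardner,65
stephens,65
payne,65
pierce,64
berry,64
matthews,64
arnold,63
wagner,63
willis,62
ray,62
watkins,62
olson,61
carroll,61
duncan,60
snyder,60
hart,60
cunningham,59
bradley,59
lane,59
andrews,59
ruiz,59
harper,58
fox,58
riley,58
armstrong,57
carpenter,57
weaver,56
greene,56
lawrence,56
elliott,55
chavez,55
sims,55
austin,55
peters,55
kelley,54
franklin,54
lawson,54
fields,53
gutierrez,53
ryan,53
schmidt,53
carr,52
vasquez,52
castillo,52
wheeler,52
chapman,51
oliver,51
montgomery,51
richards,51
williamson,50
johnston,50
banks,50
meyer,49
bishop,49
mccoy,49
howell,49
alvarez,48
morrison,48
hansen,48
fernandez,48
garza,47
harvey,47
little,47
burton,47
stanley,46
nguyen,46
george,46
jacobs,45
reid,45
kim,45
fuller,44
lynch,44
dean,44
gilbert,44
garrett,43
romero,43
welch,43
larson,43
frazier,42
burke,42
hanson,42
day,42
mendoza,42
moreno,41
bowman,41
medina,41
fowler,40
brewer,40
hoffman,40
carlson,39
silva,39
pearson,39
holland,38
douglas,38
fleming,38
jensen,38
vargas,38
byrd,37
davidson,37
hopkins,37
terry,36
herrera,36
wade,36
soto,35
walters,35
curtis,35
neal,35
caldwell,35
lowe,34
jennings,34
barnett,34
graves,34
jimenez,34
horton,33
shelton,33
barrett,33
obrien,33
castro,33
sutton,32
gregory,32
mckinney,32
lucas,32
miles,32
craig,31
rodriquez,31
chambers,31
holt,31
lambert,31
fletcher,31
watts,30
bates,30
hale,30
rhodes,30
pena,30
beck,30
newman,30
haynes,29
mcdaniel,29
mendez,29
bush,29
vaughn,29
parks,28
dawson,28
santiago,28
norris,28
hardy,28
love,28
steele,27
curry,27
powers,27
schultz,27
barker,27
guzman,26
page,26
munoz,26
ball,26
keller,26
chandler,25
weber,25
leonard,25
walsh,25
lyons,25
ramsey,24
wolfe,24
schneider,24
mullins,24
benson,24
sharp,24
bowen,24
daniel,23
barber,23
cummings,23
hines,23
baldwin,23
griffith,23
valdez,22
hubbard,22
salazar,22
reeves,22
warner,22
stevenson,22
burgess,22
santos,21
tate,21
cross,21
garner,21
mann,21
mack,21
moss,20
thornton,20
dennis,20
mcgee,20
farmer,20
delgado,20
aguilar,19
vega,19
glover,19
manning,19
cohen,19
harmon,19
rodgers,19
robbins,18
newton,18
todd,18
blair,18
higgins,18
ingram,18
reese,18
cannon,18
strickland,17
townsend,17
potter,17
goodwin,17
walton,17
rowe,17
hampton,17
ortega,17
patton,16
swanson,16
joseph,16
francis,16
goodman,16
maldonado,16
yates,16
becker,16
erickson,15
hodges,15
rios,15
conner,15
adkins,15
webster,15
norman,15
malone,15
hammond,15
flowers,15
cobb,15
moody,14
quinn,14
blake,14
maxwell,14
pope,14
floyd,14
osborne,14
paul,14
mccarthy,14
guerrero,14
lindsey,14
estrada,13
sandoval,13
gibbs,13
tyler,13
gross,13
fitzgerald,13
stokes,13
doyle,13
sherman,12
saunders,12
wise,12
colon,12
gill,12
alvarado,12
greer,12
padilla,12
simon,12
waters,12
nunez,12
ballard,12
schwartz,11
mcbride,11
houston,11
christensen,11
klein,11
pratt,11
briggs,11
parsons,11
mclaughlin,11
zimmerman,11
french,11
buchanan,11
moran,10
copeland,10
roy,10
pittman,10
brady,10
mccormick,10
holloway,10
brock,10
poole,10
frank,10
logan,10
owen,9
bass,9
marsh,9
drake,9
wong,9
jefferson,9
park,9
morton,9
abbott,9
sparks,9
patrick,8
norton,8
huff,8
clayton,8
massey,8
lloyd,8
figueroa,8
carson,8
bowers,8
roberson,8
barton,8
tran,8
lamb,7
harrington,7
casey,7
boone,7
cortez,7
clarke,7
mathis,7
singleton,7
wilkins,7
cain,7
bryan,7
underwood,7
hogan,7
mckenzie,7
collier,6
luna,6
phelps,6
mcguire,6
allison,6
bridges,6
wilkerson,6
nash,6
summers,6
atkins,6
zickerman,3
toothaker,3
roush,4
koehler,5
reinhart,4
gonzaga,3
tull,3
swan,6
przybylinski,2
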