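letter,neighbors
a,qswxz
b,fghnv
c,dfsvx
d,cefrsvwx
e,dfrsw
f,bcdegrtv
g,bfhnrtvy
h,bgjmntuy
i,jklou
j,hikmnuy
k,ijlmou
l,ikop
m,hjkn
n,bghjm
o,iklp
p,lo
q,asw
r,defgt
s,acdeqwxz
t,fghry
u,hijky
v,bcdfg
w,adeqs
x,acdsz
y,ghjtu
z,asx
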