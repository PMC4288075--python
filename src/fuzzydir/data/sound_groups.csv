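letter,group
b,1
f,1
p,1
v,1
c,2
g,2
j,2
k,2
q,2
s,2
x,2
z,2
d,3
t,3
l,4
m,5
n,5
r,6
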