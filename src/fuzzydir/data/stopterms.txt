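dr
md
do
phd
facs
faap
np
pa
rn
mr
mrs
ms
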