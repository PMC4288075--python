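canonical,nickname,likelihood
william,bill,0.9
william,will,0.45
william,billy,0.8
timothy,tim,0.8
stephen,steve,0.8
stephen,steven,0.85
steven,steve,0.8
philip,phil,0.8
phillip,phil,0.8
richard,rich,0.8
richard,rick,0.8
richard,dick,0.8
robert,bob,0.8
robert,rob,0.8
robert,bobby,0.8
james,jim,0.8
james,jimmy,0.8
john,jack,0.8
john,johnny,0.8
michael,mike,0.8
elizabeth,liz,0.8
elizabeth,beth,0.8
elizabeth,betsy,0.8
margaret,peggy,0.8
margaret,meg,0.8
katherine,kate,0.8
katherine,kathy,0.8
thomas,tom,0.8
charles,chuck,0.8
charles,charlie,0.8
joseph,joe,0.8
daniel,dan,0.8
matthew,matt,0.8
christopher,chris,0.8
anthony,tony,0.8
edward,ed,0.8
edward,ted,0.8
samuel,sam,0.8
benjamin,ben,0.8
nicholas,nick,0.8
andrew,andy,0.8
andrew,drew,0.8
david,dave,0.8
kenneth,ken,0.8
ronald,ron,0.8
donald,don,0.8
patricia,pat,0.8
patricia,patty,0.8
jennifer,jen,0.8
susan,sue,0.8
deborah,deb,0.8
deborah,debbie,0.8
barbara,barb,0.8
gregory,greg,0.8
jonathan,jon,0.8
lawrence,larry,0.8
raymond,ray,0.8
frederick,fred,0.8
alexander,alex,0.8
theodore,ted,0.8
victoria,vicky,0.8
rebecca,becky,0.8
kimberly,kim,0.8
pamela,pam,0.8
cynthia,cindy,0.8
sandra,sandy,0.8
judith,judy,0.8
christine,chris,0.8
jacqueline,jackie,0.8
abigail,abby,0.8
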