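code,common_name,group,precision_single,recall_single,f1_single,precision_two,recall_two,f1_two,support
background,Background,background,0.90,1.00,0.95,0.96,1.00,0.98,23417
bos,Feral cattle,large,0.92,0.85,0.88,0.95,0.92,0.94,6613
caae,Domestic goat,large,0.94,0.88,0.91,0.97,0.95,0.96,7535
caca,Roe deer,large,0.41,0.95,0.57,0.93,0.97,0.95,97
can,Feral dog,medium,0.96,0.94,0.95,0.95,0.99,0.97,4558
capi,Iberian ibex,large,0.95,0.93,0.94,0.98,0.98,0.98,7736
cer,Red deer,large,0.91,0.81,0.86,0.95,0.90,0.92,7197
dam,Fallow deer,large,0.24,0.92,0.38,0.73,0.94,0.82,232
equ,Feral horse,large,0.90,0.87,0.88,0.94,0.94,0.94,6915
fel,European wildcat,medium,0.54,0.97,0.70,0.89,0.97,0.93,128
fsi,Feral cat,medium,0.99,0.97,0.98,0.99,0.98,0.99,6068
gen,Small-common genet,small,0.99,0.96,0.98,0.99,0.98,0.99,5240
her,Egyptian mongoose,small,0.95,0.97,0.96,0.98,0.98,0.98,3967
lep,Hare,micro,0.96,0.93,0.95,0.98,0.95,0.97,4158
lut,Eurasian otter,small,0.83,0.95,0.88,0.96,0.98,0.97,389
lyn,Iberian lynx,medium,0.67,0.87,0.76,0.88,0.97,0.93,61
mafo,Stone marten,small,0.99,0.97,0.98,0.99,0.99,0.99,7689
mel,Eurasian badger,small,0.82,0.96,0.88,0.94,0.99,0.96,1300
mus,Mouse,micro,0.99,0.88,0.93,0.99,0.97,0.98,3283
ory,Rabbit,micro,0.67,0.91,0.77,0.92,0.96,0.94,674
ovar,Domestic sheep,large,0.95,0.91,0.93,0.99,0.95,0.97,7468
ovor,European mouflon,large,0.58,0.91,0.71,0.91,0.99,0.95,572
rara,Rat,micro,0.80,0.96,0.88,0.98,0.98,0.98,342
sus,Wild boar,large,0.94,0.90,0.92,0.96,0.95,0.95,7421
vul,Red fox,medium,0.94,0.91,0.93,0.93,0.96,0.94,7502
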