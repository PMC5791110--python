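acid,mean_kcal_mol
oxalic,-1.861
malonic,-1.952
succinic,-1.955
malic,-1.998
fumaric,-1.994
maleic,-1.964
citraconic,-1.993
itaconic,-1.988
tartaric,-1.879
glutaric,-1.961
adipic,-1.985
pimelic,-1.975
suberic,-1.969
azelaic,-1.924
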