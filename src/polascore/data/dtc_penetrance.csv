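# Missing distal-tip-cell penetrance by genotype and region.
# Percentages are as printed in the source table; counts are reconstructed at
# analysis time. "@15C" marks strains scored at 15 deg C (default 22.5 deg C).
genotype,region,pct_missing,n
N2,anterior,0.0,100
N2,posterior,0.0,100
lin-17,anterior,4.7,107
lin-17,posterior,2.8,107
lin-17@15C,anterior,11.1,54
lin-17@15C,posterior,1.9,54
lin-17; cwn-1,anterior,7.2,111
lin-17; cwn-1,posterior,0.9,111
lin-17; cwn-2,anterior,45.8,94
lin-17; cwn-2,posterior,4.3,94
lin-17; cwn-2@15C,anterior,88.5,61
lin-17; cwn-2@15C,posterior,54.1,61
lin-17; egl-20,anterior,4.4,340
lin-17; egl-20,posterior,0.0,340
lin-17; egl-20 cwn-2,anterior,2.9,70
lin-17; egl-20 cwn-2,posterior,0.0,70
lin-17; egl-20 cwn-2@15C,anterior,0.3,332
lin-17; egl-20 cwn-2@15C,posterior,3.0,332
lin-17; cwn-1; egl-20,anterior,5.8,69
lin-17; cwn-1; egl-20,posterior,1.5,69
lin-17; cwn-1; egl-20@15C,anterior,1.3,78
lin-17; cwn-1; egl-20@15C,posterior,1.3,78
lin-17; cwn-1; cwn-2,anterior,89.1,46
lin-17; cwn-1; cwn-2,posterior,78.3,46
lin-17; cwn-1; cwn-2@15C,anterior,100.0,42
lin-17; cwn-1; cwn-2@15C,posterior,97.6,42
lin-17; cwn-1; egl-20 cwn-2,anterior,86.8,53
lin-17; cwn-1; egl-20 cwn-2,posterior,84.9,53
lin-17; cwn-1; egl-20 cwn-2@15C,anterior,97.8,46
lin-17; cwn-1; egl-20 cwn-2@15C,posterior,95.7,46
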