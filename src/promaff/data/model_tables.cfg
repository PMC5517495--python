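# Default model tables.
# pwm_logodds: 15-column natural-log odds vs a uniform background,
#   TATA consensus TATAWAWR at columns 4-11, pseudocount 0.25.
# slide: nearest-neighbour duplex stacking free energies
#   (kcal/mol, 37C, unified scale); less negative = easier opening.
# bend: dimer-step propeller-twist magnitudes (degrees) as a
#   deformability proxy.
# Calibration absorbs affine rescaling of either dinucleotide scale.
format_version = 1
pwm_width = 15
pwm_logodds =
A  0  0  0  -0.69314718055994529  0.91629073187415511  -0.69314718055994529  0.91629073187415511  0.40546510810816438  0.91629073187415511  0.40546510810816438  0.40546510810816438  0  0  0  0
C  0  0  0  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  0  0  0  0
G  0  0  0  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  -0.69314718055994529  0.40546510810816438  0  0  0  0
T  0  0  0  0.91629073187415511  -0.69314718055994529  0.91629073187415511  -0.69314718055994529  0.40546510810816438  -0.69314718055994529  0.40546510810816438  -0.69314718055994529  0  0  0  0
slide =
AA  -1
AC  -1.4399999999999999
AG  -1.28
AT  -0.88
CA  -1.45
CC  -1.8400000000000001
CG  -2.1699999999999999
CT  -1.28
GA  -1.3
GC  -2.2400000000000002
GG  -1.8400000000000001
GT  -1.4399999999999999
TA  -0.57999999999999996
TC  -1.3
TG  -1.45
TT  -1
bend =
AA  18.66
AC  13.1
AG  14
AT  15.01
CA  9.9299999999999997
CC  8.1099999999999994
CG  10.029999999999999
CT  14
GA  13.48
GC  11.08
GG  8.1099999999999994
GT  13.1
TA  11.85
TC  13.48
TG  9.9299999999999997
TT  18.66
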