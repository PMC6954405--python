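# Default square-well depths e(a,b) for receptor-peptide SC-SC contacts.
# Hydrophobicity-derived symmetric scale: e(a,b) = -(0.2 + h_a*h_b),
# h = min-max normalized Kyte-Doolittle hydropathy. Dimensionless units.
A C D E F G H I K L M N P Q R S T V W Y
A -0.690 -0.744 -0.278 -0.278 -0.768 -0.519 -0.301 -0.900 -0.247 -0.846 -0.698 -0.278 -0.426 -0.278 -0.200 -0.488 -0.496 -0.877 -0.480 -0.449
C -0.744 -0.805 -0.286 -0.286 -0.831 -0.554 -0.312 -0.978 -0.252 -0.917 -0.753 -0.286 -0.451 -0.286 -0.200 -0.520 -0.528 -0.952 -0.511 -0.477
D -0.278 -0.286 -0.212 -0.212 -0.290 -0.251 -0.216 -0.311 -0.207 -0.302 -0.279 -0.212 -0.236 -0.212 -0.200 -0.246 -0.247 -0.307 -0.244 -0.240
E -0.278 -0.286 -0.212 -0.212 -0.290 -0.251 -0.216 -0.311 -0.207 -0.302 -0.279 -0.212 -0.236 -0.212 -0.200 -0.246 -0.247 -0.307 -0.244 -0.240
F -0.768 -0.831 -0.290 -0.290 -0.858 -0.570 -0.317 -1.011 -0.254 -0.948 -0.777 -0.290 -0.461 -0.290 -0.200 -0.533 -0.542 -0.984 -0.524 -0.488
G -0.519 -0.554 -0.251 -0.251 -0.570 -0.408 -0.266 -0.656 -0.230 -0.620 -0.524 -0.251 -0.347 -0.251 -0.200 -0.387 -0.392 -0.640 -0.382 -0.362
H -0.301 -0.312 -0.216 -0.216 -0.317 -0.266 -0.221 -0.344 -0.210 -0.333 -0.303 -0.216 -0.247 -0.216 -0.200 -0.259 -0.261 -0.340 -0.258 -0.251
I -0.900 -0.978 -0.311 -0.311 -1.011 -0.656 -0.344 -1.200 -0.267 -1.122 -0.911 -0.311 -0.522 -0.311 -0.200 -0.611 -0.622 -1.167 -0.600 -0.556
K -0.247 -0.252 -0.207 -0.207 -0.254 -0.230 -0.210 -0.267 -0.204 -0.261 -0.247 -0.207 -0.221 -0.207 -0.200 -0.227 -0.228 -0.264 -0.227 -0.224
L -0.846 -0.917 -0.302 -0.302 -0.948 -0.620 -0.333 -1.122 -0.261 -1.050 -0.856 -0.302 -0.497 -0.302 -0.200 -0.579 -0.589 -1.091 -0.569 -0.528
M -0.698 -0.753 -0.279 -0.279 -0.777 -0.524 -0.303 -0.911 -0.247 -0.856 -0.706 -0.279 -0.429 -0.279 -0.200 -0.492 -0.500 -0.887 -0.484 -0.453
N -0.278 -0.286 -0.212 -0.212 -0.290 -0.251 -0.216 -0.311 -0.207 -0.302 -0.279 -0.212 -0.236 -0.212 -0.200 -0.246 -0.247 -0.307 -0.244 -0.240
P -0.426 -0.451 -0.236 -0.236 -0.461 -0.347 -0.247 -0.522 -0.221 -0.497 -0.429 -0.236 -0.304 -0.236 -0.200 -0.332 -0.336 -0.511 -0.329 -0.315
Q -0.278 -0.286 -0.212 -0.212 -0.290 -0.251 -0.216 -0.311 -0.207 -0.302 -0.279 -0.212 -0.236 -0.212 -0.200 -0.246 -0.247 -0.307 -0.244 -0.240
R -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200 -0.200
S -0.488 -0.520 -0.246 -0.246 -0.533 -0.387 -0.259 -0.611 -0.227 -0.579 -0.492 -0.246 -0.332 -0.246 -0.200 -0.369 -0.374 -0.597 -0.364 -0.346
T -0.496 -0.528 -0.247 -0.247 -0.542 -0.392 -0.261 -0.622 -0.228 -0.589 -0.500 -0.247 -0.336 -0.247 -0.200 -0.374 -0.378 -0.608 -0.369 -0.350
V -0.877 -0.952 -0.307 -0.307 -0.984 -0.640 -0.340 -1.167 -0.264 -1.091 -0.887 -0.307 -0.511 -0.307 -0.200 -0.597 -0.608 -1.134 -0.587 -0.544
W -0.480 -0.511 -0.244 -0.244 -0.524 -0.382 -0.258 -0.600 -0.227 -0.569 -0.484 -0.244 -0.329 -0.244 -0.200 -0.364 -0.369 -0.587 -0.360 -0.342
Y -0.449 -0.477 -0.240 -0.240 -0.488 -0.362 -0.251 -0.556 -0.224 -0.528 -0.453 -0.240 -0.315 -0.240 -0.200 -0.346 -0.350 -0.544 -0.342 -0.326
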