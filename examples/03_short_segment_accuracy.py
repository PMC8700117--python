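"""How well do short segments reproduce the full-length MSE curve?

A long 1/f series is cut into short overlapping windows; a multiscale variant
is computed per window and averaged per scale; the averaged curve is scored
by its mean squared difference from the full-length MSE reference.  Sweeping
the fuzzy exponent over a grid gives an error surface whose per-length argmin
is the optimal exponent n*(L).
"""

import numpy as np

from msentropy import error_surface, gen_pink_noise, optimal_exponents

series = [gen_pink_noise(2000, seed=s) for s in (11, 12)]
lengths = [400, 800]
grid = np.round(np.arange(0.8, 1.21, 0.1), 2)

for variant in ("MFE", "RCMSE"):
    surf = error_surface(series, variant, lengths, grid, tau_max=8)
    print(f"{variant}: mean squared error vs full-length MSE")
    print(surf.to_frame().to_string(index=False))
    if surf.estimator == "fuzzy":
        print("optimal exponents:", optimal_exponents(surf))
    print()
print("Lower error = the windowed variant reproduces the reference better.")
print("On Gaussian 1/f noise the sample-entropy variants track the (sample-")
print("entropy) reference closely, while the fuzzy variants carry a")
print("systematic offset that the exponent grid can only partly absorb; on")
print("empirical RR series the fuzzy estimators are the more robust choice")
print("at short lengths because hard counting degrades or becomes undefined.")
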