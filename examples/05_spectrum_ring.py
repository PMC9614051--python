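"""Leading eigenvalue ring of an idealized feedforward cluster matrix.

The block-circulant closed form: N_C clusters of m neurons connected only
cluster i -> i+1 with weight w have nonzero eigenvalues m*w*exp(2 pi i k/N_C)
— the ring that signals cyclic feedforward structure in a trained network.
"""

import numpy as np

from neuralclock.analysis import full_spectrum
from neuralclock.fixtures import make_ring_matrix

N_C, m, w = 10, 5, 0.3
W = make_ring_matrix(N_C, m, 0.0, w)
spec = full_spectrum(W, n_leading=N_C)

expected = m * w * np.exp(2j * np.pi * np.arange(N_C) / N_C)
print(f"{N_C} clusters of {m}, feedforward weight {w} -> ring radius m*w = {m*w}")
print("leading eigenvalues (sorted) vs closed form:")
for got, exp in zip(np.sort_complex(spec.leading), np.sort_complex(expected)):
    print(f"  {got.real:+.6f}{got.imag:+.6f}j   expected "
          f"{exp.real:+.6f}{exp.imag:+.6f}j")
err = np.abs(np.sort_complex(spec.leading) - np.sort_complex(expected)).max()
print(f"max deviation: {err:.2e}")
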