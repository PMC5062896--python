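"""Galton-Watson extinction filter for newly founded clones.

A clone starts from one mitotic cell; a division keeps both progeny mitotic
with probability a^2, one with 2a(1-a), none with (1-a)^2.  The chance the
lineage dies out is the smaller root of f(x) = x, i.e. ((1-a)/a)^2 for
a > 1/2 and certain extinction otherwise.
"""
import numpy as np

from hemaclone import clone_survives, extinction_probability

for a in (0.5, 0.6, 0.87, 0.95, 1.0):
    print(f"  a = {a:4.2f}: extinction probability p_e = {extinction_probability(a):.4f}")

# Monte-Carlo check at a = 0.6: survival should be 1 - 4/9 = 5/9
rng = np.random.default_rng(0)
n = 50_000
frac = sum(clone_survives(0.6, rng) for _ in range(n)) / n
print(f"empirical survival at a=0.6 over {n} draws: {frac:.4f} (theory {5/9:.4f})")
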