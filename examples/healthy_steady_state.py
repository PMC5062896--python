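"""Feedback-regulated healthy hematopoiesis: signal, steady state, recovery.

The mitotic compartment self-renews with probability a_max * s(t), where the
cytokine-like signal s = 1/(1 + k*c2) falls as mature cells accumulate.  The
closed-form steady state is c2_bar = (2*a_max - 1)/k, c1_bar = d*c2_bar/p.
"""
import numpy as np
from scipy.integrate import solve_ivp

from hemaclone import HealthyParams, feedback_signal, healthy_steady_state

hp = HealthyParams()  # a_max=0.87, p=0.45/day, d=2.3/day, k=1.85e-9
c1_bar, c2_bar = healthy_steady_state(hp)
s_bar = feedback_signal(c2_bar, 0.0, hp.k)

print(f"steady state: c1_bar = {c1_bar:.4g} cells, c2_bar = {c2_bar:.4g} cells")
print(f"feedback signal at steady state: s = {s_bar:.5f}"
      f"  (realized self-renewal a_max*s = {hp.a_max * s_bar:.5f} = 1/2)")

# perturb the system and watch it relax back
def rhs(t, y):
    c1, c2 = y
    s = feedback_signal(c2, 0.0, hp.k)
    return [(2 * hp.a_max * s - 1) * hp.p * c1,
            2 * (1 - hp.a_max * s) * hp.p * c1 - hp.d * c2]

sol = solve_ivp(rhs, (0, 365), [0.3 * c1_bar, 0.3 * c2_bar], method="LSODA",
                rtol=1e-10, atol=1.0, t_eval=[0, 30, 90, 365])
for t, c1, c2 in zip(sol.t, *sol.y):
    print(f"  day {t:5.0f}: c1/c1_bar = {c1 / c1_bar:.3f}, c2/c2_bar = {c2 / c2_bar:.3f}")
print("after one year the perturbed system is back at the fixed point.")
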