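"""Fit thermal expansion for a single structure family.

Builds a small variable-temperature series of unit cells (an isotropic cubic
toy crystal and a realistic monoclinic one), runs the principal-axis
analysis and prints the coefficients.  All values are referenced to 298 K
and quoted in p.p.m. per kelvin.
"""

import pandas as pd

from thermex import fit_single_family

# Isotropic toy family: every length grows 2% over 200 K, so each principal
# coefficient is 0.02/200 K = 1e-4 /K at the 100 K reference, i.e. 98.06
# p.p.m./K once referenced to 298 K, and alpha_V is about three times that.
iso = pd.DataFrame(
    {
        "a": [10.0, 10.2], "b": [10.0, 10.2], "c": [10.0, 10.2],
        "alpha": [90.0, 90.0], "beta": [90.0, 90.0], "gamma": [90.0, 90.0],
        "temperature_K": [100.0, 300.0],
    }
)
res = fit_single_family(iso)
print("isotropic cubic family (2 temperature points)")
print(f"  alpha_L(298 K) per axis : {res.alpha_l[0]:.2f} p.p.m./K (x3)")
print(f"  alpha_V(298 K)          : {res.alpha_v.alpha_v_298:.1f} p.p.m./K")
print(f"  sum of alpha_L          : {res.sum_alpha_l:.1f} p.p.m./K "
      "(matches alpha_V to first order)")
print(f"  NTE class               : {res.nte_class}\n")

# Monoclinic family: the twofold axis pins one principal axis to b exactly;
# the two others lie in the a-c plane.
mono = pd.DataFrame(
    {
        "a": [6.00, 6.02, 6.05], "b": [8.00, 8.03, 8.05], "c": [10.00, 10.05, 10.11],
        "alpha": [90.0] * 3, "beta": [104.0, 104.12, 104.30], "gamma": [90.0] * 3,
        "temperature_K": [100.0, 200.0, 293.0],
    }
)
res = fit_single_family(mono)
print("monoclinic family (3 temperature points)")
print(f"  alpha_V(298 K) : {res.alpha_v.alpha_v_298:.1f} "
      f"({res.alpha_v.su_alpha_v:.1f}) p.p.m./K, R^2 = {res.alpha_v.r_squared:.4f}")
for i in range(3):
    axis = " ".join(f"{x:+.3f}" for x in res.principal_axes[i])
    print(f"  alpha_L{i + 1}(298 K): {res.alpha_l[i]:8.1f} p.p.m./K along [{axis}]")
print(f"  anisotropy     : {res.anisotropy:.3f}   NTE class: {res.nte_class}")
print("  (one axis is exactly [0 1 0]: the monoclinic b axis)")
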