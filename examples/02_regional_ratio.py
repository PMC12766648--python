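"""Sensitivity-corrected regional sSNV-count ratio with the mixing null.

Builds a variant table with a planted 1.5x excess of low-mosaic variants in
one region, then estimates the ratio of detectable variants between the two
regions and compares it with the uniformly-mixed null.
"""

from clonetrace.regional_ratio import SensitivityCurve, estimate_ratio_ci
from clonetrace.simulate import planted_regional_excess

variants = planted_regional_excess(
    n_shared=60, n_excess=30, region_a="BA17", region_b="BA18",
    mf_band=(0.02, 0.04), seed=3,
)
est = estimate_ratio_ci(
    variants, "BA17", "BA18", SensitivityCurve.default(),
    n_iter=1000, ci_level=0.95, seed=1,
)
print(f"observed ratio BA17/BA18: {est.observed:.2f} "
      f"(95% CI {est.observed_ci[0]:.2f}-{est.observed_ci[1]:.2f})")
print(f"expected under uniform mixing: {est.expected:.2f} "
      f"(95% CI {est.expected_ci[0]:.2f}-{est.expected_ci[1]:.2f})")
print(f"empirical p = {est.p_value:.4f}; significant: {est.significant}")
# The observed interval sits near the planted 1.5x excess while the null
# interval hugs 1; a small empirical p declares the regional difference real.
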