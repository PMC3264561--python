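"""Mutant presets: altered biosynthesis (yuc), polarization (pid), PIN level (pin).

Each preset scales one physiological parameter relative to wild type:

* ``yuc``  scales local auxin production and the boundary inflow together
  (reduced biosynthesis in the rescued yuc1 yuc4 background);
* ``pid``  scales the endosome-to-membrane PIN cycling rate k1
  (reduced polarization capacity in weak pinoid alleles);
* ``pin``  scales the fixed amount of PIN per cell (defective PIN1;
  20% of nominal mimics the strong pin-formed phenotype).

The strong pin mutant no longer forms separated maxima: elevated auxin
appears as a concentric outer ring, and almost no initiation sites form
inside the whorl circle.
"""

import numpy as np

from florasim.experiments import ExperimentSpec, preset_params, run_single


def elevated_geometry(trace, params):
    """Fraction of elevated-auxin cells inside the whorl circle at the end."""
    s = trace.final
    hot = (s.auxin > 0.5 * params.transport.A_threshold) | s.differentiated
    (cx, cy), radius = trace.tissue_center_radius()
    r = np.hypot(s.centroids[:, 0] - cx, s.centroids[:, 1] - cy) / radius
    frac = float(
        (r[hot] < params.analysis.whorl_radius_fraction).mean()
    ) if hot.any() else float("nan")
    return int(hot.sum()), frac


for preset, scale in [("wildtype", 1.0), ("yuc", 0.5), ("pid", 0.5), ("pin", 0.2)]:
    spec = ExperimentSpec(preset=preset, scale=scale)
    trace, report = run_single(spec, seed=3)
    params = preset_params(preset, scale)
    n_hot, inner = elevated_geometry(trace, params)
    print(
        f"{preset:9s} x{scale:<4}  pattern {report.pattern}  "
        f"elevated cells {n_hot:4d}  inner fraction {inner:.3f}"
    )

print()
print("Reduced biosynthesis (yuc 0.5) lowers petal and reproductive counts")
print("while sepal number stays near four; at 20% PIN the elevated cells sit")
print("almost entirely in the outer ring (inner fraction ~0), matching the")
print("missing inner whorls of strong pin mutants.")
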