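"""Relax curve and surface semilandmarks by bending-energy minimization.

Perturbs the semilandmarks of the built-in toy mandible along their
tangent directions and slides them back; the printed log shows the
thin-plate-spline bending energy dropping at the tangent step of every
iteration.
"""

import numpy as np

from ontotraj import OntogenySpec, base_shape, slide_semilandmarks

coords, labels, scheme = base_shape(OntogenySpec())
rng = np.random.default_rng(0)

specimens = []
for _ in range(3):
    x = coords.copy()
    idx = scheme.sliding_indices
    x[idx] += 0.01 * rng.normal(size=(len(idx), 3))
    specimens.append(x)

result = slide_semilandmarks(
    np.array(specimens), scheme, reference=coords, iterations=3,
    back_project=False,
)

print("bending energy per outer iteration (specimen 0):")
for it, i, before, after, _ in result.energy_log:
    if i == 0:
        print(f"  iteration {it}: {before:.3e} -> {after:.3e}")

moved = np.linalg.norm(result.coords[0] - specimens[0], axis=1)
print(f"\nlargest semilandmark displacement: {moved.max():.4f}")
print(f"fixed landmarks moved: {moved[scheme.fixed].max():.1e} (never)")
print("\nsliding removes the arbitrary along-curve/within-surface placement")
print("of semilandmarks, leaving only shape signal for the analysis.")
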