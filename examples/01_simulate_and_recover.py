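"""Simulate a rodent-like ontogeny and recover its planted trajectory
statistics with the full pipeline.

The generator defaults emulate a 3-species x 5-stage breeding design
(6 specimens per cell) with front-loaded growth in the mouse-like
species; the printed comparison shows how well noisy data recover the
planted per-day rates and path distances (bias-corrected estimates, with
sampled standard errors).
"""

from ontotraj import OntogenySpec, PipelineConfig, generate_dataset, run_pipeline

spec = OntogenySpec(seed=42)
dataset, truth = generate_dataset(spec)
print(f"simulated {dataset.n} specimens, {dataset.k} landmarks each\n")

result = run_pipeline(dataset, PipelineConfig(n_perm=500, n_draws=500, seed=42))

print("path distances (Procrustes units): planted vs recovered ± SE")
for row in result.path_table.itertuples():
    planted = truth.path_distances[row.species]
    print(
        f"  {row.species:8s} {planted:.3f} vs "
        f"{row.path_corrected:.3f} ± {row.se_path:.3f}"
    )

print("\nper-day rates, 7-14 days: planted vs recovered")
g = result.growth_table
for row in g[g.age_from == 7].itertuples():
    planted = truth.rates[row.species][0]
    print(f"  {row.species:8s} {planted:.4f} vs {row.rate_corrected:.4f}")

print("\nA rate near 0.021/day in the mouse-like species against ~0.010 in")
print("the others reproduces the front-loaded mouse ontogeny the defaults")
print("encode; path distances are similar across species by construction.")
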