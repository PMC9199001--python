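"""Generate a seeded synthetic count dataset and inspect its structure.

The generator emulates the study geometry: 20 healthy participants, 16
non-overlapping 400 µm × 400 µm confocal images (0.16 mm² each) per corneal
region, participant true densities drawn from gamma distributions matched
to the published healthy-cornea summaries (central 21.7 ± 17.7 cells/mm²,
peripheral 62.0 ± 26.1 cells/mm²), and Poisson per-image counting noise.
"""

from icdensity import GeneratorConfig, generate_counts

config = GeneratorConfig(seed=1)
dataset = generate_counts(config)

print(f"records: {dataset.n_records}  (participants x regions x images)")
print(dataset.frame.head(4).to_string(index=False))

true_means = dataset.true_means(reference_size=16)
summary = true_means.groupby("region")["true_mean"].agg(["mean", "std"])
print("\nper-region 'true mean' density across participants (cells/mm2):")
print(summary.round(1).to_string())
print(
    "\nEach participant-region's true mean is the average density over its\n"
    "16-image reference set (2.56 mm2 of quantified tissue); the between-\n"
    "participant spread mirrors the published healthy-cornea summaries."
)

report = dataset.validate(reference_size=16)
print(f"\nvalidation findings: {len(report.findings)} (clean dataset)")
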