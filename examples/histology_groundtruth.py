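"""Histology ground truth: droplet counting, size statistics, labelling.

Renders synthetic stained liver sections for both groups, segments the
lipid droplets, bins them by equivalent diameter (2-7 and 7-13 px), runs
the per-bin ANOVA, and applies the droplet-count labelling rule.
"""

import numpy as np

from hepatoscope.histology import (
    compare_groups,
    healthy_section_spec,
    label_from_droplets,
    nafld_section_spec,
    render_section,
    segment_droplets,
    size_distribution,
)

rng = np.random.default_rng(0)
groups = {}
for name, spec_fn in (("healthy", healthy_section_spec), ("nafld", nafld_section_spec)):
    hists = []
    for _ in range(10):
        s = int(rng.integers(0, 2**31 - 1))
        table = segment_droplets(render_section(spec_fn(seed=s), seed=s))
        hists.append(size_distribution(table, group=name))
    groups[name] = hists
    small = [h.counts[0] for h in hists]
    large = [h.counts[1] for h in hists]
    print(f"{name:8}: small droplets (diam 2-7 px) {np.mean(small):5.1f} +- {np.std(small):.1f}, "
          f"large (7-13 px) {np.mean(large):4.1f} +- {np.std(large):.1f}")

# fatty sections show a marked excess of small droplets; ANOVA per bin
anova = compare_groups(groups["healthy"], groups["nafld"])
print("\nper-bin one-way ANOVA (healthy vs fatty):")
print(anova.to_string(index=False))

labels = {name: [label_from_droplets(h) for h in hists] for name, hists in groups.items()}
correct = sum(l == "healthy" for l in labels["healthy"]) + sum(l == "nafld" for l in labels["nafld"])
print(f"\ndroplet-rule labels match the generating group for {correct}/20 sections")
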