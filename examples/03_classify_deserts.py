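"""End-to-end run: simulate, call DMRs, classify them as CpG deserts.

A CpG desert is a 500-2000 bp differentially methylated region with
< 15 CpG/100 bp overall density, at least one small CpG cluster and no
CpG island. The planted desert loci draw their densities from the
1-8 CpG/100 bp band, so essentially every called DMR should fall below
10 CpG/100 bp — the signature this package exists to quantify. The last
block renders one called DMR as a text map (hatch marks = CpG sites).
"""
from cpgdesert import (
    ExperimentSpec,
    call_dmrs,
    classify_dmr_set,
    make_genome_spec,
    plan_runs_for_deserts,
    probe_median_difference,
    probe_pvalues,
    render_dmr_map,
    simulate_genome,
    simulate_probe_experiment,
)

gspec = make_genome_spec(seed=11, length=2_000_000, n_deserts=20, n_islands=5, grid=100)
rec, truth = simulate_genome(gspec)
runs = plan_runs_for_deserts(truth.desert_intervals(), spacing=100, width=5, delta=5.0)
espec = ExperimentSpec(seed=12, n_probes=20_000, spacing=100, planted=runs)
design, intensities, _ = simulate_probe_experiment(espec)

stats = probe_pvalues(probe_median_difference(intensities), list(intensities.probe_ids))
calls = call_dmrs(design, stats, alpha=1e-5, min_adjacent=3)
table, summary = classify_dmr_set(rec, [c.interval for c in calls])

print(f"{len(calls)} DMRs called; {summary['n_desert']} classify as CpG deserts")
print(f"{100 * summary['fraction_density_lt_10']:.1f}% of called DMRs have "
      f"density < 10 CpG/100 bp "
      f"(median {summary['density_median']:.1f}, max {summary['density_max']:.1f})")
print()
print(render_dmr_map(rec, calls[0].interval))
# most calls fail the desert length bound only when the caller recovered a
# truncated (<500 bp) probe run; their density still sits in the desert band
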