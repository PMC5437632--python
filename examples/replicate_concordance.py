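"""Replicate reproducibility and noise characterization.

Thirteen synthetic control samples, each sequenced in three replicate
libraries, carry reproducible true variants plus planted noise present in
only some replicates. Concordance is measured per region class, and the
validated DP/VF thresholds are checked against the non-reproducible calls.
"""

from germpanel import SimulationConfig, characterize_noise, replicate_concordance
from germpanel.simulate import make_callsets, make_panel
from germpanel.valstats import ReplicateSet, surviving_noise_count
from germpanel.variants import apply_filters, union_merge

config = SimulationConfig(seed=5)
panel = make_panel(config)
controls, _ = make_callsets(config, panel)

prefilter = {
    cid: [apply_filters(union_merge(r.calls_a, r.calls_b), panel) for r in reps]
    for cid, reps in controls.items()
}
table, sweep, ok = characterize_noise(prefilter)
n_noise = int((~table["reproducible"]).sum())
print(f"{len(table)} distinct calls across {len(controls)} controls; "
      f"{n_noise} non-reproducible (noise)")
print(f"noise surviving DP>=50, VF>=20%/25%: {surviving_noise_count(table)} "
      f"(thresholds eliminate all noise: {ok})")

print("\nper-control concordance of filtered calls:")
for cid in list(controls)[:4]:
    filtered = [[c for c in rep if c.filter_status == "pass"]
                for rep in prefilter[cid]]
    rs = ReplicateSet(cid, filtered,
                      [r.run_label for r in controls[cid]],
                      [r.barcode for r in controls[cid]])
    out = replicate_concordance(rs)
    print(f"  {cid}: exonic identical={out['all_identical_exonic']}, "
          f"noncoding Jaccard={out['jaccard_noncoding']:.2f}, "
          f"discordant={out['n_discordant']} "
          f"(borderline-explained {out['borderline_explained']:.0%})")

# Exonic call sets are identical across replicates; what discordance
# appears is confined to noncoding calls that barely clear the thresholds
# (the borderline flag), matching the assay's validation behaviour.
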