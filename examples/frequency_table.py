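"""Gene-selection frequency across repeated runs.

Repeats the full selection three times with derived seeds and counts, for
every gene, the outer-fold selection events that included it.  Genes
selected in at least 4 of the 15 fold-level events are flagged frequent.

Note what this does and does not show: with an accuracy-only fitness and
several redundant planted markers, a single marker per class suffices for
a perfect tree, so the swarm has no pressure to keep the other markers in
every mask — frequency separates planted from background genes only
weakly at this scale.  Recovery of the planted set is measured on the
union mask instead (see select_genes.py).
"""

from psodt import CVConfig, PSOParams, SyntheticSpec, gene_selection_frequency, generate
from psodt.selection import repeat_runs

synth = generate(SyntheticSpec(n_samples=48, n_genes=40, n_informative=4, seed=5))
summary = repeat_runs(
    synth.dataset, pso=PSOParams(T=10, n_particles=8),
    cv=CVConfig(k=5), n_runs=3, master_seed=5, inner_k=3,
)

for rec in summary.runs:
    print(f"run {rec.run}: accuracy {rec.accuracy_pct:.2f}% | {rec.n_selected} genes")
print(f"Avg. {summary.mean_accuracy_pct:.2f}  (Std. {summary.std_accuracy_pct:.2f})")

freq = gene_selection_frequency(summary.results, threshold=4)
planted = set(synth.dataset.gene_names[synth.informative_indices])
print(f"\ntop of the frequency table ({freq.n_events} selection events; * = planted):")
for _, row in freq.table.head(8).iterrows():
    marker = " *" if row["gene"] in planted else ""
    print(f"  {row['gene']}  frequency {row['frequency']}"
          f"  frequent={bool(row['frequent'])}{marker}")
# Frequency counts how many of the 15 fold-level selections kept a gene.
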