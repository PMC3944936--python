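"""Nested cross-validated gene selection on synthetic planted-marker data.

Generates a 60-sample x 100-gene matrix with 5 informative genes shifted
by 3 standard deviations in one class, runs the swarm-plus-tree selection
with a five-fold outer protocol, and reports per-fold held-out accuracy
and how much of the planted set the union of fold masks recovered.
"""

from psodt import CVConfig, PSOParams, SyntheticSpec, generate, recovery_metrics
from psodt.selection import run_psodt

synth = generate(SyntheticSpec(n_samples=60, n_genes=100, n_informative=5, seed=0))
result = run_psodt(
    synth.dataset, pso=PSOParams(T=30, n_particles=20),
    cv=CVConfig(k=5), seed=0, inner_k=3,
)

for fr in result.folds:
    print(f"fold {fr.fold}: held-out accuracy {fr.test_accuracy:.3f} | "
          f"{int(fr.mask.sum())} genes selected | swarm fitness {fr.fitness:.3f}")
recall, precision = recovery_metrics(result, synth)
print(f"mean outer accuracy : {result.mean_accuracy:.3f}")
print(f"union of fold masks : {result.n_union} genes "
      f"(recall of planted set {recall:.2f}, precision {precision:.2f})")
# Held-out accuracy ~0.9 shows the selected subsets carry the planted
# signal; recall 1.0 means every informative gene appears in some fold's
# mask, while low precision reflects that accuracy-only fitness has no
# pressure to drop uninformative genes.
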