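"""Evaluate a candidate set against known disease annotations.

The fourth-layer candidates are compared with an annotated gene/miRNA list
over the network node set as background: confusion-matrix metrics plus the
inclusive upper-tail hypergeometric p-value of the overlap.
"""

from topcontrol import RunConfig, evaluate_candidates, hypergeom_upper_tail, layer_members, run
from topcontrol.model import DiseaseAnnotation
from topcontrol.synthetic import SyntheticSpec, generate

catalog, expression, annotation, _ = generate(SyntheticSpec(seed=1))
result = run(RunConfig(), catalog=catalog, expression=expression, annotation=annotation)

report = result.evaluation
c = report.counts
print(f"universe N = {c.universe_n}, annotated K = {c.disease_k}, candidates n = {c.candidate_n}")
print(f"tp = {c.tp}, fp = {c.fp}, fn = {c.fn}, tn = {c.tn}")
print("percent metrics:", report.percentages())
print(f"overlap significance: p = {report.hyper_p:.4f}")

# The same machinery reproduces a published liver-cancer result: 17 of 82
# candidates annotated, in a 275-node network containing 33 annotated nodes.
p = hypergeom_upper_tail(17, 275, 33, 82)
print(f"liver-cancer fourth-layer overlap: p = {p:.4f} (rounds to 0.004)")
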