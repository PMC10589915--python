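"""How expression data become per-target regression problems.

Time-series rows discretize dx_j/dt + c x_j = f_j(regulators) with a forward
difference; steady-state rows use the equilibrium identity c x_j =
f_j(regulators).  The responses below can be checked by hand.
"""

import numpy as np

from grnfusion import (ExpressionDataset, GeneIndex, OdeConfig, SteadyStateMatrix,
                       TimeSeriesExperiment, assemble_design)

genes = GeneIndex(("A", "B", "C"))
# target A rises 1 -> 2 -> 4 over unit steps; with decay c = 1 the responses
# are (2-1)/1 + 1 = 2 and (4-2)/1 + 2 = 4
experiment = TimeSeriesExperiment(
    times=np.array([0.0, 1.0, 2.0]),
    values=np.array([[1.0, 0.3, 1.1],
                     [2.0, 0.6, 0.9],
                     [4.0, 1.2, 1.0]]))
steady = SteadyStateMatrix(np.array([[3.0, 0.5, 0.8],
                                     [1.5, 0.2, 1.4]]))
dataset = ExpressionDataset(genes, [experiment], steady)

design = assemble_design(dataset, target="A", regulators=["B", "C"],
                         cfg=OdeConfig(decay_rate=1.0, lag=1))
print(f"design matrix for target A ({design.n_rows} rows = (3-1) time-series"
      " + 2 steady):")
print(f"{'provenance':<12} {'B':>6} {'C':>6} {'response':>9}")
for tag, row, y in zip(design.row_provenance, design.features, design.responses):
    print(f"{tag:<12} {row[0]:>6.2f} {row[1]:>6.2f} {y:>9.2f}")
print("\ntime-series responses are the discretized derivative plus decay;")
print("steady responses are c * x_A (here 3.0 and 1.5); features are the")
print("regulator levels at the earlier time / same condition.")
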