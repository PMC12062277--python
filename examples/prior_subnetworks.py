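"""Build a prior graph by shortest-path reconstruction from a background PPI.

Starting from seed genes of interest, extracts the union of all shortest
paths between seed pairs from a background interaction network, then
restricts the result to the features actually measured in an assay.
"""

import networkx as nx

from graphomix.priors import (ModalityGraphSpec, restrict_to_measured,
                              shortest_path_subnetwork)

# toy background PPI: two hubs bridging three seed genes
background = nx.Graph([
    ("APP", "APOE"), ("APOE", "CLU"), ("CLU", "TREM2"),
    ("APP", "PSEN1"), ("PSEN1", "TREM2"), ("APP", "MAPT"),
    ("MAPT", "BIN1"), ("BIN1", "TREM2"), ("SORL1", "CLU"),
])
seeds = {"APP", "TREM2", "SORL1"}

sub = shortest_path_subnetwork(background, seeds)
print(f"seeds: {sorted(seeds)}")
print(f"subnetwork: {sub.number_of_nodes()} nodes, "
      f"{sub.number_of_edges()} edges")
for u, v in sorted(map(sorted, sub.edges())):
    print(f"  {u} -- {v}")

spec = ModalityGraphSpec.from_networkx(sub, name="toy-biodomain")
measured = {"APP", "APOE", "CLU", "TREM2", "SORL1"}  # assay coverage
restricted = restrict_to_measured(spec, measured)
print(f"after restricting to {len(measured)} measured features: "
      f"{restricted.n_nodes} nodes, {restricted.n_edges} edges")
# All nodes on any shortest seed-to-seed path are kept (both branches of a
# tie), then unmeasured intermediates are dropped with edges induced.
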