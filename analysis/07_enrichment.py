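#!/usr/bin/env python
"""Pathway over-representation of the selected features.

Real pathway content depends on annotation and database versions, so this
driver builds a labelled synthetic library over the detected-feature
background: one pathway deliberately loaded with selected features, plus
background pathways of random membership, each with a chain-like reaction
graph for the betweenness topology score.  Fisher ORA + BH + impact are
then computed exactly as they would be on a real library
(results/07_enrich/).
"""

import argparse
import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from pfasmet.enrichment import PathwayLibrary, ora_fisher

parser = argparse.ArgumentParser()
parser.add_argument("--differential", type=Path, default=Path("results/05_differential"))
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/07_enrich"))
args = parser.parse_args()

sel = pd.read_csv(args.differential / "differential.tsv", sep="\t",
                  index_col="feature_id")
background = list(sel.index)
selected = list(sel.index[sel["selected"]])
rng = np.random.default_rng(args.seed)

pathways, graphs = {}, {}
# a "perturbed" pathway: half its members drawn from the selected set
k = max(6, min(20, 2 * len(selected)))
hit_members = list(rng.choice(selected, size=min(len(selected), k // 2),
                              replace=False))
others = [f for f in background if f not in hit_members]
members = hit_members + list(rng.choice(others, size=k - len(hit_members),
                                        replace=False))
pathways["perturbed_pathway"] = set(members)
graphs["perturbed_pathway"] = nx.path_graph(members)
for i in range(5):
    members = list(rng.choice(background, size=int(rng.integers(8, 25)),
                              replace=False))
    pid = f"background_pathway_{i + 1}"
    pathways[pid] = set(members)
    graphs[pid] = nx.path_graph(members)

library = PathwayLibrary(pathways=pathways, background=set(background),
                         graphs=graphs)
results = ora_fisher(selected, library, with_topology=True)

args.out.mkdir(parents=True, exist_ok=True)
library.to_json(args.out / "library.json")
frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
frame.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)

for r in sorted(results, key=lambda r: r.p):
    mark = " *" if r.significant else ""
    print(f"{r.pathway}: overlap {r.overlap}/{r.size}, p={r.p:.2e}, "
          f"FDR={r.fdr:.2e}, impact={r.impact:.3f}{mark}")
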