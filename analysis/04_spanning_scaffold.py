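#!/usr/bin/env python
"""Basal scaffold of the group network: Maximum Spanning Forest and Tree.

Keeps each region's single strongest link (directed MSF), summarises the
resulting modules (sizes, reciprocated pairs, chain scores), completes the
forest to the Maximum Spanning Tree, and contrasts the in-degree profile of
the real network (chain-like, max in-degree ~2) with its spectrum-preserving
randomizations (star-like, hubs of in-degree ~7+). Writes the component and
edge tables under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from fcscaffold.nullmodel import ensemble_generate
from fcscaffold.spanning import (
    component_summary,
    degree_profiles,
    msf_rowmax,
    mst_complete,
)
from fcscaffold.timeseries import read_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--group-matrix", default="scratch/group_r.tsv")
    ap.add_argument("--n-null", type=int, default=100)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    r, labels = read_matrix(args.group_matrix)
    w = r**2
    np.fill_diagonal(w, 0.0)

    forest = msf_rowmax(w)
    profile = degree_profiles(forest)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    component_summary(forest, labels).to_csv(out / "msf_components.tsv", sep="\t", index=False)
    lines = ["source\ttarget\tweight\treciprocated"] + [
        f"{labels[s]}\t{labels[t]}\t{wt:.10g}\t{frozenset((s, t)) in forest.reciprocated_pairs}"
        for s, t, wt in forest.arcs
    ]
    (out / "msf_arcs.tsv").write_text("\n".join(lines) + "\n")

    tree = mst_complete(forest, w)
    tree_profile = degree_profiles(tree)
    lines = ["source\ttarget\tweight"] + [
        f"{labels[a]}\t{labels[b]}\t{wt:.10g}" for a, b, wt in tree.edges
    ]
    (out / "mst_edges.tsv").write_text("\n".join(lines) + "\n")

    ensemble = ensemble_generate(r, n=args.n_null, master_seed=args.seed)
    null_profiles = [degree_profiles(msf_rowmax(m)) for m in ensemble.squared()]
    null_max = [p.max_degree for p in null_profiles]

    summary = {
        "msf_n_components": len(forest.components),
        "msf_component_sizes": sorted((len(c) for c in forest.components), reverse=True),
        "msf_reciprocated_pairs": len(forest.reciprocated_pairs),
        "msf_in_degree_histogram": profile.counts,
        "msf_chain_score": profile.chain_score,
        "null_msf_max_in_degree_mean": float(np.mean(null_max)),
        "null_msf_max_in_degree_range": [int(min(null_max)), int(max(null_max))],
        "mst_total_weight": tree.total_weight,
        "mst_degree_histogram": tree_profile.counts,
        "mst_chain_score": tree_profile.chain_score,
    }
    (out / "scaffold_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    frac1 = profile.fractions.get(1, 0.0)
    print(f"MSF: {summary['msf_n_components']} components, "
          f"{summary['msf_reciprocated_pairs']} reciprocated pairs, "
          f"{100 * frac1:.0f}% of in-degrees equal to 1 (chain-like)")
    print(f"null MSF max in-degree {np.mean(null_max):.1f} on average "
          f"(range {min(null_max)}-{max(null_max)}) vs real {profile.max_degree} "
          "-> star-like nulls, chain-like brain")
    print(f"MST: total weight {tree.total_weight:.3f}, chain score "
          f"{tree_profile.chain_score:.2f}, degree histogram {tree_profile.counts}")


if __name__ == "__main__":
    main()
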