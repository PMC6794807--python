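#!/usr/bin/env python
"""Co-expression module detection and module-trait correlation.

Scans soft-threshold powers for scale-free fit (falling back to the
study's power of 10 when the 9-sample network never reaches the target),
builds the topological overlap matrix, cuts average-linkage modules, and
correlates module eigengenes with the binary glucose and TTR traits to
nominate the hub module.
"""

import argparse
from pathlib import Path

from ttrnet.coexpression import (
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    topological_overlap,
)
from ttrnet.io import read_dataset, round6
from ttrnet.pipeline import _default_traits


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--cut-height", type=float, default=0.9)
    ap.add_argument("--min-module-size", type=int, default=10)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    matrix, *_ = read_dataset(args.dataset)
    expr = matrix.log2p1()
    scan = pick_soft_threshold(expr)
    flag = " (fallback)" if scan.used_fallback else ""
    print(f"soft threshold: beta = {scan.chosen_beta}{flag}")
    round6(scan.table).to_csv(args.out_dir / "soft_threshold_scan.tsv", sep="\t")

    tom = topological_overlap(expr, scan.chosen_beta)
    mods = detect_modules(tom, args.min_module_size, args.cut_height)
    sizes = mods.labels.value_counts()
    print("modules:", dict(sizes))
    mods.labels.rename_axis("transcript_id").to_frame().to_csv(
        args.out_dir / "modules.tsv", sep="\t"
    )

    eig = module_eigengene(expr, mods)
    round6(eig.scores.rename_axis("module")).to_csv(args.out_dir / "eigengenes.tsv", sep="\t")
    traits = _default_traits(matrix.design, ("LG", "HG", "HG_TTR"))
    res = module_trait_correlation(eig, traits)
    flat = res.correlations.copy()
    flat.columns = [f"{t}_{k}" for t, k in flat.columns]
    round6(flat.rename_axis("module")).to_csv(args.out_dir / "module_trait.tsv", sep="\t")
    print("module-trait correlations:")
    print(res.correlations.round(3).to_string())
    print(f"hub module (max of min |r| over both traits): {res.hub_module}")


if __name__ == "__main__":
    main()
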