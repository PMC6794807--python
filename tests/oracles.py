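"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from first principles, without calling
the package implementation it is checked against.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up written out literally."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def scan_seed_sites(target: str, mirna: str) -> list[tuple[int, str]]:
    """Exhaustive sliding-window seed scan; returns (1-based start, class)."""
    target = target.upper().replace("U", "T")
    mirna = mirna.upper().replace("U", "T")
    core = mirna[1:7] if len(mirna) >= 8 else mirna[:6]
    m8 = mirna[7] if len(mirna) >= 8 else mirna[6]
    want = revcomp(core)
    hits = []
    for i in range(len(target) - 5):
        if target[i : i + 6] != want:
            continue
        has_m8 = i > 0 and target[i - 1] == _COMP[m8]
        has_a1 = i + 6 < len(target) and target[i + 6] == "A"
        cls = (
            "8mer"
            if has_m8 and has_a1
            else "7mer-m8"
            if has_m8
            else "7mer-A1"
            if has_a1
            else "6mer"
        )
        hits.append((i + 1, cls))
    return hits


def all_pairs_cis(table, lnc_ids, mrna_ids, window):
    """Quadratic interval-distance scan; returns {(lnc, mrna): (relation, gap)}."""
    out = {}
    for ln in lnc_ids:
        for mr in mrna_ids:
            if ln == mr:
                continue
            a, b = table.loc[ln], table.loc[mr]
            if a["chrom"] != b["chrom"]:
                continue
            if b["start"] <= a["end"] and a["start"] <= b["end"]:
                rel, gap = "overlapping", 0
            elif b["end"] < a["start"]:
                rel, gap = "upstream", int(a["start"] - b["end"])
            else:
                rel, gap = "downstream", int(b["start"] - a["end"])
            if gap <= window:
                out[(ln, mr)] = (rel, gap)
    return out


def all_pairs_trans(expr, lnc_ids, mrna_ids, r_threshold):
    """Per-pair np.corrcoef scan; returns {(lnc, mrna): r}."""
    out = {}
    for ln in lnc_ids:
        for mr in mrna_ids:
            if ln == mr:
                continue
            r = float(np.corrcoef(expr.loc[ln], expr.loc[mr])[0, 1])
            if abs(r) >= r_threshold:
                out[(ln, mr)] = r
    return out
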