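"""Recovery scoring: best-match F1 against reference communities.

The headline metric is the one-directional average F1: each reference
community is matched to the detected community maximizing F1 (harmonic
mean of precision and recall on the member sets) and the per-reference
maxima are averaged.  Detected communities can also be ranked by
persistence to trace recovery as a function of the number of reported
communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "f1", "average_f1", "rank_by_persistence", "f1_curve"]


def f1(ref, det) -> float:
    """F1 of a detected set against a reference set (0 when disjoint)."""
    ref, det = set(ref), set(det)
    if not ref:
        raise ValueError("reference community must be nonempty")
    if not det:
        return 0.0
    inter = len(ref & det)
    if inter == 0:
        return 0.0
    precision = inter / len(det)
    recall = inter / len(ref)
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Per-reference best matches and the aggregate average F1."""

    table: pd.DataFrame  # index: reference name; columns: best_match, precision, recall, f1, jaccard, recovered
    average_f1: float

    def recovered(self, jaccard_threshold: float = 0.5) -> int:
        """Number of references with a highly overlapping detected match."""
        return int((self.table["jaccard"] > jaccard_threshold).sum())


def _as_named(detected) -> list[tuple[str, set]]:
    if isinstance(detected, dict):
        return [(str(k), set(v)) for k, v in detected.items()]
    width = len(str(max(len(detected), 1)))
    return [(f"D{i:0{width}d}", set(d)) for i, d in enumerate(detected)]


def average_f1(refs: dict, detected) -> EvalReport:
    """Average, over references, of the F1 with the best-matching detection.

    ``refs`` maps name -> node set; ``detected`` is a list of node sets or
    a name -> set mapping.  Best-match ties break by larger Jaccard, then
    lexicographic detected name.  An empty detected collection scores 0.
    """
    if not refs:
        raise ValueError("reference set must be nonempty")
    named = _as_named(detected)
    rows = []
    for rname in sorted(refs):
        ref = set(refs[rname])
        best = ("", 0.0, 0.0, 0.0, 0.0)  # name, f1, jaccard, precision, recall
        for dname, det in named:
            score = f1(ref, det)
            inter = len(ref & det)
            jac = inter / (len(ref) + len(det) - inter) if det else 0.0
            key = (score, jac, _NegStr(dname))
            best_key = (best[1], best[2], _NegStr(best[0]))
            if best[0] == "" or key > best_key:
                prec = inter / len(det) if det else 0.0
                rec = inter / len(ref)
                best = (dname, score, jac, prec, rec)
        rows.append(
            {
                "reference": rname,
                "best_match": best[0],
                "precision": best[3],
                "recall": best[4],
                "f1": best[1],
                "jaccard": best[2],
                "recovered": best[2] > 0.5,
            }
        )
    table = pd.DataFrame(rows).set_index("reference")
    return EvalReport(table=table, average_f1=float(table["f1"].mean()))


class _NegStr(str):
    """String ordered reversed, so max() prefers the lexicographic smallest."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def rank_by_persistence(h, top_n: int | None = None) -> list[frozenset]:
    """Non-root communities by descending persistence, truncated to top_n.

    Ties break by larger size then lexicographic smallest member — the
    same ordering used to trace recovery-vs-model-complexity curves.
    """
    ranked = [h.members[v] for v in h.communities()]
    if top_n is not None:
        ranked = ranked[: max(0, top_n)]
    return ranked


def f1_curve(refs: dict, h, max_n: int | None = None) -> pd.DataFrame:
    """Average F1 against the top-N persistence-ranked communities, per N."""
    ranked = rank_by_persistence(h)
    if max_n is not None:
        ranked = ranked[:max_n]
    rows = []
    for n in range(1, len(ranked) + 1):
        rows.append({"top_n": n, "average_f1": average_f1(refs, ranked[:n]).average_f1})
    return pd.DataFrame(rows)
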