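"""Evaluation protocols for the pair classifier.

Two protocols are implemented: a precision/recall sweep over the score
threshold (varied from 1 down to 0, strict-greater labelling), and a
ranked-list evaluation on hub proteins (genes with more than 50 known PPIs)
where each hub's candidate partners are sorted by score and cumulative true
vs false positives are counted top to bottom.  "False positives" in the
ranked lists are unlabeled pairs treated as negatives — an evaluation
convention, since some are likely undiscovered true interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annot_io import AnnotationUniverse, Pair, PPIEdgeList, canonical_pair
from .model import HiPPIPClassifier

HUB_MIN_DEGREE = 50


@dataclass
class PRCurve:
    """Precision/recall at every score threshold, descending from 1 to 0."""

    table: pd.DataFrame  # columns: threshold, precision, recall, TP, FP, FN, zero_predictions

    def at_threshold(self, threshold: float) -> pd.Series:
        """Confusion counts in force at *threshold*.

        Prediction sets are constant between consecutive swept score values,
        so the row with the largest swept threshold <= the requested one has
        exactly the prediction set of strict-greater thresholding there.
        """
        at_or_below = self.table[self.table["threshold"] <= threshold]
        if len(at_or_below):
            idx = at_or_below["threshold"].idxmax()
        else:
            idx = self.table["threshold"].idxmin()
        return self.table.loc[idx]


def pr_sweep(scores: Sequence[float], labels: Sequence[int]) -> PRCurve:
    """Sweep the decision threshold and tabulate the confusion counts.

    A pair is predicted positive iff score > threshold (consistent with
    ``classify``).  Precision at zero predictions is reported as 1.0 with the
    ``zero_predictions`` flag set.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("empty score set")
    n_pos = int(y.sum())
    thresholds = sorted({1.0, 0.0} | set(s.tolist()), reverse=True)
    rows = []
    for t in thresholds:
        pred = s > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        n_pred = tp + fp
        precision = tp / n_pred if n_pred else 1.0
        recall = tp / n_pos if n_pos else 0.0
        rows.append(
            dict(
                threshold=t,
                precision=precision,
                recall=recall,
                TP=tp,
                FP=fp,
                FN=fn,
                zero_predictions=(n_pred == 0),
            )
        )
    return PRCurve(pd.DataFrame(rows))


def identify_hubs(known: PPIEdgeList, min_degree: int = HUB_MIN_DEGREE) -> set[str]:
    """Genes whose degree in the known-PPI graph is strictly above *min_degree*."""
    return {g for g, d in known.degrees().items() if d > min_degree}


@dataclass
class RankedListEval:
    """Per-hub ranked-list curves plus the cross-hub average.

    ``per_hub`` maps hub -> DataFrame (rank, score, partner, is_tp,
    cum_TP, cum_FP); ``average`` tabulates mean cumulative TP at each
    false-positive count across hubs (hubs whose list ends early contribute
    their final TP value).
    """

    per_hub: dict[str, pd.DataFrame]
    average: pd.DataFrame = field(default_factory=pd.DataFrame)


def _hub_curve(
    model: HiPPIPClassifier,
    hub: str,
    universe: AnnotationUniverse,
    heldout_partners: set[str],
    threshold_floor: float,
) -> pd.DataFrame:
    candidates = [
        canonical_pair(hub, g) for g in universe.catalog.symbols if g != hub
    ]
    partners = [b if a == hub else a for a, b in candidates]
    scores = model.decision_scores(candidates)
    keep = scores > threshold_floor
    ranked = sorted(
        zip(scores[keep], np.asarray(partners, dtype=object)[keep]),
        key=lambda t: (-t[0], t[1]),
    )
    rows = []
    tp = fp = 0
    for rank, (score, partner) in enumerate(ranked, start=1):
        is_tp = partner in heldout_partners
        tp += is_tp
        fp += not is_tp
        rows.append(
            dict(rank=rank, score=float(score), partner=partner,
                 is_tp=bool(is_tp), cum_TP=tp, cum_FP=fp)
        )
    return pd.DataFrame(rows, columns=["rank", "score", "partner", "is_tp", "cum_TP", "cum_FP"])


def average_curve(per_hub: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean cumulative TP at each FP count across hub ranked lists."""
    nonempty = {h: df for h, df in per_hub.items() if len(df)}
    if not nonempty:
        return pd.DataFrame(columns=["FP", "mean_TP"])
    max_fp = max(int(df["cum_FP"].iloc[-1]) for df in nonempty.values())
    rows = []
    for x in range(0, max_fp + 1):
        vals = []
        for df in nonempty.values():
            within = df[df["cum_FP"] <= x]
            vals.append(int(within["cum_TP"].iloc[-1]) if len(within) else 0)
        rows.append(dict(FP=x, mean_TP=float(np.mean(vals))))
    return pd.DataFrame(rows)


def hub_ranked_eval(
    model: HiPPIPClassifier,
    hubs: Sequence[str],
    universe: AnnotationUniverse,
    heldout_edges: Sequence[Pair],
    threshold_floor: float = 0.5,
) -> RankedListEval:
    """Ranked-list TP-vs-FP evaluation for each hub gene.

    Candidates are hub x (catalog - hub); only pairs scoring strictly above
    *threshold_floor* are retained, sorted by descending score with ties
    broken by partner symbol.  A retained partner counts as TP iff the
    (hub, partner) edge is among the held-out known edges.
    """
    heldout = {canonical_pair(a, b) for a, b in heldout_edges}
    per_hub: dict[str, pd.DataFrame] = {}
    for hub in hubs:
        h = universe.catalog.canonicalize(hub)
        if h is None:
            raise KeyError(f"hub {hub!r} not in catalog")
        partners = {
            b if a == h else a for a, b in heldout if h in (a, b)
        }
        per_hub[h] = _hub_curve(model, h, universe, partners, threshold_floor)
    return RankedListEval(per_hub=per_hub, average=average_curve(per_hub))
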