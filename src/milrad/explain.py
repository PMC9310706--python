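"""Per-subject attention reports: which nodules drove the diagnosis.

The attention weights (alpha) are softmax-normalized within a subject, so
they are comparable only within that subject — never across subjects.  A
nodule with alpha below ``alpha_floor`` (default 0.01) is flagged as not
influential for the recommendation.
"""

from __future__ import annotations

import pandas as pd

from .model import MILResults
from .schema import Bag

__all__ = ["attention_report", "report_to_dataframe", "ALPHA_CAVEAT"]

ALPHA_CAVEAT = (
    "attention weights are normalized within each subject and are only "
    "comparable between nodules of the same subject, never across subjects"
)


def attention_report(
    bags: list[Bag], results: MILResults, alpha_floor: float = 0.01
) -> list[dict]:
    """One record per subject: bag probability and ranked nodule attention.

    Each record lists the subject's nodules sorted by descending alpha with
    an ``influential`` flag (alpha >= alpha_floor).  Deterministic given the
    fitted model and input bags.
    """
    preds = results.attention(bags)
    records = []
    for bag, pred in zip(bags, preds):
        alphas = pred.instance_attention()
        nodules = [
            {
                "nodule_id": nid,
                "alpha": alpha,
                "influential": bool(alpha >= alpha_floor),
            }
            for nid, alpha in sorted(alphas.items(), key=lambda kv: -kv[1])
        ]
        records.append(
            {
                "subject_id": bag.subject_id,
                "bag_prob": pred.bag_prob,
                "label": bag.label,
                "nodules": nodules,
                "caveat": ALPHA_CAVEAT,
            }
        )
    return records


def report_to_dataframe(records: list[dict]) -> pd.DataFrame:
    """Flatten the per-subject report to one row per nodule (CSV-friendly)."""
    rows = []
    for rec in records:
        for rank, nod in enumerate(rec["nodules"]):
            rows.append(
                {
                    "subject_id": rec["subject_id"],
                    "bag_prob": rec["bag_prob"],
                    "label": rec["label"],
                    "rank": rank,
                    "nodule_id": nod["nodule_id"],
                    "alpha": nod["alpha"],
                    "influential": nod["influential"],
                }
            )
    return pd.DataFrame(rows)
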