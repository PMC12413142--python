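"""Segmentation agreement via the Dice similarity coefficient (DSC).

DSC(A, B) = 2|A ∩ B| / (|A| + |B|), in [0, 1]; 1 means identical masks.
Multi-class label images are scored one-vs-rest per label.  When both masks
are empty the coefficient is defined as 1 (perfect agreement on absence)
and flagged, since the ratio is otherwise 0/0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bodycomp import AlignmentError, ValidationError

logger = logging.getLogger("ctcomp")

__all__ = ["DiceReport", "dice", "dice_suite"]


@dataclass
class DiceReport:
    label: Optional[str]
    size_a: int
    size_b: int
    intersection: int
    dsc: float
    both_empty: bool = False

    def as_dict(self) -> dict:
        return {
            "label": self.label, "size_a": self.size_a, "size_b": self.size_b,
            "intersection": self.intersection, "dsc": self.dsc,
            "both_empty": self.both_empty,
        }


def dice(mask_a: np.ndarray, mask_b: np.ndarray, label: Optional[str] = None) -> DiceReport:
    """Dice coefficient of two boolean masks by exact integer set arithmetic."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    if na + nb == 0:
        return DiceReport(label=label, size_a=0, size_b=0, intersection=0,
                          dsc=1.0, both_empty=True)
    return DiceReport(label=label, size_a=na, size_b=nb, intersection=inter,
                      dsc=2.0 * inter / (na + nb))


def dice_suite(
    reference: Sequence[np.ndarray],
    candidate: Sequence[np.ndarray],
    classes: Sequence[int] | None = None,
    class_names: dict[int, str] | None = None,
    out_dir=None,
) -> tuple[list[dict], dict]:
    """Per-case, per-class DSC for paired label images, plus mean/SD per class.

    ``reference`` and ``candidate`` are equal-length sequences of integer
    label images (or boolean masks when ``classes`` is None, scored as a
    single foreground class).  Returns (per-case rows, summary); the summary
    maps each class to its mean and sample SD of DSC across cases.
    """
    if len(reference) != len(candidate):
        raise ValidationError(
            f"unpaired cases: {len(reference)} reference vs {len(candidate)} candidate"
        )
    rows: list[dict] = []
    for i, (ref, cand) in enumerate(zip(reference, candidate)):
        ref = np.asarray(ref)
        cand = np.asarray(cand)
        labels = classes if classes is not None else [1]
        for lab in labels:
            name = (class_names or {}).get(lab, str(lab))
            if classes is None:
                rep = dice(ref.astype(bool), cand.astype(bool), label=name)
            else:
                rep = dice(ref == lab, cand == lab, label=name)
            rows.append({"case": i, "class": name, **rep.as_dict()})

    summary: dict = {}
    df = pd.DataFrame(rows)
    for name, grp in df.groupby("class", sort=True):
        vals = grp["dsc"].to_numpy(float)
        summary[str(name)] = {
            "n_cases": int(vals.size),
            "mean_dsc": float(vals.mean()),
            "sd_dsc": float(vals.std(ddof=1)) if vals.size >= 2 else None,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df[["case", "class", "size_a", "size_b", "intersection", "dsc"]].to_csv(
            out_dir / "dice.csv", index=False
        )
        (out_dir / "dice_summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("wrote Dice evaluation to %s", out_dir)
    return rows, summary
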