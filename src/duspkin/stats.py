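"""Quantification and comparison statistics for the experimental readouts.

Implements the ddCt relative-quantification arithmetic (target Ct normalized
to the mean of two housekeeping genes, fold change 2**-ddCt against a
reference sample), a two-sample Z-test on group means with independent
standard errors, and a concordance stage that checks whether the directions
observed in a cell-count table match the kinetic model's predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ValidationError
from .synth import CellCountTable, CtTable, HOUSEKEEPING_GENES
from .trajectories import RegimeLabel

__all__ = ["FoldChangeTable", "ConcordanceReport", "delta_delta_ct",
           "z_test_counts", "concordance"]


@dataclass(frozen=True)
class FoldChangeTable:
    """Per (sample, target gene): dCt, ddCt and fold change 2**-ddCt."""

    data: pd.DataFrame  # sample, gene, delta_ct, delta_delta_ct, fold_change
    reference_sample: str
    housekeeping: tuple[str, ...]

    def fold(self, sample: str, gene: str) -> float:
        sel = (self.data["sample"] == sample) & (self.data["gene"] == gene)
        if not sel.any():
            raise ValidationError(f"no fold change for ({sample}, {gene})")
        return float(self.data.loc[sel, "fold_change"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class ConcordanceReport:
    """Per condition: model-predicted vs observed direction of the Herceptin
    response, with the Z-test p-value backing the observed call."""

    data: pd.DataFrame
    alpha: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "alpha": self.alpha,
            "conditions": self.data.to_dict(orient="records"),
        }, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"Model-experiment concordance (alpha={self.alpha})"]
        for row in self.data.to_dict(orient="records"):
            mark = "agree" if row["agree"] else (
                "non-informative" if not row["informative"] else "DISAGREE"
            )
            lines.append(
                f"  {row['condition']:>9}: model={row['model_direction']:<11} "
                f"observed={row['observed_direction']:<8} "
                f"p={row['p_value']:.3g}  [{mark}]"
            )
        return "\n".join(lines)


def delta_delta_ct(
    ct: CtTable,
    housekeeping: "tuple[str, ...] | list[str]" = HOUSEKEEPING_GENES,
    reference_sample: str | None = None,
) -> FoldChangeTable:
    """Relative quantification of every non-housekeeping gene in every sample.

    dCt = mean Ct(target) - mean Ct(housekeeping) per sample;
    ddCt = dCt(sample) - dCt(reference); fold = 2**-ddCt.  The two
    housekeeping genes are combined by the arithmetic mean of their Ct, so
    the result is invariant to their order.  When ``reference_sample`` is
    None, each sensitivity group's non-targeting (NT) sample is its own
    reference (the usual contrast for knockdown efficiency).
    """
    housekeeping = tuple(housekeeping)
    df = ct.data
    mean_ct = (
        df.groupby(["sample", "gene"], sort=True)["ct"].mean().unstack("gene")
    )
    missing = [g for g in housekeeping if g not in mean_ct.columns]
    if missing:
        raise ValidationError(f"housekeeping genes absent from table: {missing}")
    if mean_ct[list(housekeeping)].isna().any().any():
        bad = mean_ct.index[mean_ct[list(housekeeping)].isna().any(axis=1)]
        raise ValidationError(
            f"housekeeping genes missing for samples: {list(bad)}"
        )
    hk_mean = mean_ct[list(housekeeping)].mean(axis=1)
    targets = [g for g in mean_ct.columns if g not in housekeeping]

    sample_meta = df.drop_duplicates("sample").set_index("sample")
    rows = []
    for sample in mean_ct.index:
        if reference_sample is not None:
            ref = reference_sample
        else:
            sens = sample_meta.loc[sample].get("sensitivity")
            ref = f"{sens}_NT" if sens is not None else None
        if ref is None or ref not in mean_ct.index:
            raise ValidationError(
                f"reference sample {ref!r} not present in the Ct table"
            )
        for gene in targets:
            t_ct = mean_ct.loc[sample, gene]
            r_ct = mean_ct.loc[ref, gene]
            if np.isnan(t_ct) or np.isnan(r_ct):
                raise ValidationError(
                    f"gene {gene!r} missing for sample {sample!r} or "
                    f"reference {ref!r}"
                )
            d_ct = float(t_ct - hk_mean.loc[sample])
            d_ct_ref = float(r_ct - hk_mean.loc[ref])
            dd_ct = d_ct - d_ct_ref
            rows.append({
                "sample": sample,
                "gene": gene,
                "reference": ref,
                "delta_ct": d_ct,
                "delta_delta_ct": dd_ct,
                "fold_change": float(2.0 ** (-dd_ct)),
            })
    return FoldChangeTable(
        data=pd.DataFrame(rows),
        reference_sample=reference_sample or "per-sensitivity NT",
        housekeeping=housekeeping,
    )


def z_test_counts(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Z-test on means with independent standard errors.

    z = (mean_a - mean_b) / sqrt(se_a**2 + se_b**2), two-sided p from the
    standard normal.  Identical groups give z = 0, p = 1; zero spread in
    both groups leaves the statistic undefined and raises ValidationError.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValidationError(
            "zero pooled standard error with unequal means: Z-test undefined"
        )
    z = float(diff / np.sqrt(se2))
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def _model_direction(prediction) -> str:
    """Normalize a prediction (RegimeLabel, bool 'eventually decreases', or
    direction string) to 'decrease' / 'no-decrease'."""
    if isinstance(prediction, RegimeLabel):
        return ("decrease"
                if prediction in (RegimeLabel.INFLECTED, RegimeLabel.DECREASING)
                else "no-decrease")
    if isinstance(prediction, bool):
        return "decrease" if prediction else "no-decrease"
    s = str(prediction).lower().replace("_", "-")
    if s in ("decrease", "decreasing", "inflected"):
        return "decrease"
    if s in ("no-decrease", "increase", "increasing", "none"):
        return "no-decrease"
    raise ValidationError(f"cannot interpret model prediction {prediction!r}")


def concordance(
    predictions: dict,
    table: CellCountTable,
    alpha: float = 0.05,
    sensitivity: str = "resistant",
    herceptin: bool = True,
) -> ConcordanceReport:
    """Score model-experiment agreement per silencing condition.

    ``predictions`` maps silencing conditions (e.g. 'shDUSP16') to the model
    outcome for the corresponding scenario (silencing maps to elevated d5
    under the appropriate DUSP-induction topology; NT is the reference).
    The observed direction is the sign of (silenced - NT) means, called only
    when the Z-test p-value is below ``alpha``; otherwise it is 'none' and
    the condition is flagged non-informative.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    nt = table.condition(sensitivity, "NT", herceptin)
    rows = []
    for cond in sorted(predictions):
        model_dir = _model_direction(predictions[cond])
        silenced = table.condition(sensitivity, cond, herceptin)
        z, p = z_test_counts(silenced, nt)
        if p < alpha:
            observed = "decrease" if z < 0 else "increase"
        else:
            observed = "none"
        informative = observed != "none"
        agree = informative and (
            (model_dir == "decrease" and observed == "decrease")
            or (model_dir == "no-decrease" and observed == "increase")
        )
        rows.append({
            "condition": cond,
            "model_direction": model_dir,
            "observed_direction": observed,
            "z": z,
            "p_value": p,
            "informative": informative,
            "agree": agree,
        })
    return ConcordanceReport(data=pd.DataFrame(rows), alpha=alpha)
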