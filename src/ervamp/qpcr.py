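"""qPCR relative-expression arithmetic: 2^-ddCt with reference-gene
normalization, triplicate SD gating, and the RT+/RT- contamination check.

The comparative-Ct model assumes ~100% amplification efficiency, so one
cycle equals a two-fold difference in template. Expression of a target
gene is normalized to the arithmetic mean of the reference-gene Cts
(equivalent to the geometric mean of their quantities) and expressed
relative to a calibrator dCt — the mean or median dCt of the control
group. A no-RT control that amplifies within ~3.3 cycles of the RT+
reaction (less than a 10-fold quantity ratio) flags genomic-DNA
contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel returned by :func:`gate_replicates` for noisy triplicates
REJECTED = None


@dataclass
class CtMeasurement:
    """Replicate Ct values for one (sample, gene), with an optional no-RT
    control Ct. ``None``/NaN replicates are "undetermined" and dropped
    before gating."""

    sample: str
    gene: str
    cts: Sequence[float | None]
    rt_minus_ct: float | None = None

    def detected(self) -> list[float]:
        return [c for c in self.cts if c is not None and math.isfinite(c)]


def gate_replicates(m: CtMeasurement | Sequence[float],
                    max_sd: float = 0.2) -> float | None:
    """Mean Ct of the detected replicates, or REJECTED if their sample
    standard deviation is not strictly below ``max_sd``."""
    cts = m.detected() if isinstance(m, CtMeasurement) else \
        [c for c in m if c is not None and math.isfinite(c)]
    if len(cts) < 2:
        raise ValueError("replicate gating requires >= 2 detected replicates")
    if float(np.std(cts, ddof=1)) >= max_sd:
        return REJECTED
    return float(np.mean(cts))


def delta_ct(target_ct: float, ref_cts: Sequence[float]) -> float:
    """dCt = Ct_target - mean(reference Cts)."""
    refs = list(ref_cts)
    if not refs:
        raise ValueError("at least one reference gene Ct required")
    return target_ct - float(np.mean(refs))


def ddct_expression(target_ct: float, ref_cts: Sequence[float],
                    calibrator_dct: float) -> float:
    """Fold expression 2^-(dCt - calibrator dCt)."""
    return 2.0 ** -(delta_ct(target_ct, ref_cts) - calibrator_dct)


def rt_contamination_ratio(rt_plus_ct: float,
                           rt_minus_ct: float | None,
                           min_ratio: float = 10.0) -> tuple[float, bool]:
    """RT+/RT- quantity ratio 2^(Ct_minus - Ct_plus) and a pass flag.

    An undetected RT- reaction (``None``) means no amplifiable DNA:
    the ratio is infinite and the check passes.
    """
    if rt_minus_ct is None or not math.isfinite(rt_minus_ct):
        return math.inf, True
    ratio = 2.0 ** (rt_minus_ct - rt_plus_ct)
    return ratio, ratio >= min_ratio


# --------------------------------------------------------- cohort analysis

def analyze_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    groups: Mapping[str, str],
    control_group: str,
    calibrator: str = "mean",
    max_sd: float = 0.2,
) -> pd.DataFrame:
    """Per-sample fold expression of ``target_gene`` across a cohort.

    ``ct_table`` is long-format with columns ``sample, gene, replicate, ct``
    (and optionally ``rt_flag`` with values ``+``/``-``). Replicates are
    gated per (sample, gene); a sample is dropped (flagged in the output)
    if the target or any reference gene fails the gate. The calibrator dCt
    is the ``mean`` or ``median`` dCt of the control group.
    """
    if calibrator not in ("mean", "median"):
        raise ValueError("calibrator must be 'mean' or 'median'")
    table = ct_table.copy()
    if "rt_flag" in table.columns:
        table = table[table["rt_flag"].astype(str) != "-"]

    mean_ct: dict[tuple[str, str], float | None] = {}
    for (sample, gene), sub in table.groupby(["sample", "gene"]):
        mean_ct[(sample, gene)] = gate_replicates(sub["ct"].tolist(), max_sd)

    rows = []
    for sample in sorted({s for s, _ in mean_ct}):
        tgt = mean_ct.get((sample, target_gene))
        refs = [mean_ct.get((sample, g)) for g in reference_genes]
        ok = tgt is not None and all(r is not None for r in refs)
        rows.append({
            "sample": sample,
            "group": groups.get(sample),
            "gated_ok": ok,
            "dct": delta_ct(tgt, refs) if ok else np.nan,
        })
    out = pd.DataFrame(rows).set_index("sample")

    controls = out[(out["group"] == control_group) & out["gated_ok"]]
    if controls.empty:
        raise ValueError(f"no gated control samples in group {control_group!r}")
    agg = np.mean if calibrator == "mean" else np.median
    cal = float(agg(controls["dct"].to_numpy()))
    out["calibrator_dct"] = cal
    out["fold_expression"] = 2.0 ** -(out["dct"] - cal)
    return out


def rt_qc_table(ct_table: pd.DataFrame, max_sd: float = 0.2,
                min_ratio: float = 10.0) -> pd.DataFrame:
    """Per (sample, gene) RT+/RT- contamination ratios from a long-format
    table carrying an ``rt_flag`` column."""
    if "rt_flag" not in ct_table.columns:
        raise ValueError("rt_flag column required for RT+/RT- QC")
    rows = []
    for (sample, gene), sub in ct_table.groupby(["sample", "gene"]):
        plus = sub[sub["rt_flag"].astype(str) == "+"]["ct"].tolist()
        minus = sub[sub["rt_flag"].astype(str) == "-"]["ct"].tolist()
        if not plus:
            continue
        plus_ct = gate_replicates(plus, max_sd) if len(plus) >= 2 else plus[0]
        if plus_ct is None:
            continue
        minus_ct = float(np.mean(minus)) if minus else None
        ratio, ok = rt_contamination_ratio(plus_ct, minus_ct, min_ratio)
        rows.append({"sample": sample, "gene": gene, "rt_plus_ct": plus_ct,
                     "rt_minus_ct": minus_ct, "ratio": ratio, "pass": ok})
    return pd.DataFrame(rows)


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return table
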