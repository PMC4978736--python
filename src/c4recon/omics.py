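"""Differential contrasts for the three omics layers (mature vs immature).

Transcript abundances arrive as FPKM per replicate (or as a precomputed
differential-expression table), protein abundances as per-channel log2
isobaric-label ratios, metabolites as concentrations.  For each feature the
contrast of interest is mature vs immature tissue: a log2 fold change
(mature in the numerator, by convention), a two-group test (Welch by
default, or a simple empirical-Bayes moderated variant for the low-replicate
proteome), and Benjamini-Hochberg adjusted p-values within each omics layer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .homology import normalize_gene_id
from .model import SchemaError

CONDITION_A = "mature"  # numerator of every fold change
CONDITION_B = "immature"

DEFAULT_FPKM_PSEUDOCOUNT = 1.0
DEFAULT_PRIOR_DF = 4.0


class UndefinedValueError(ValueError):
    """A fold change is undefined (all-zero group with zero pseudocount)."""


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary statistics


def log2_fold_change(
    group_a: Sequence[float], group_b: Sequence[float], pseudocount: float = 0.0
) -> float:
    """log2((mean_a + pseudocount) / (mean_b + pseudocount))."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    num = float(np.mean(group_a)) + pseudocount
    den = float(np.mean(group_b)) + pseudocount
    if num <= 0 or den <= 0:
        raise UndefinedValueError(
            "fold change undefined: nonpositive group mean with this pseudocount"
        )
    return math.log2(num / den)


def two_group_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "welch",
    prior_var: float | None = None,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> tuple[float, float]:
    """Two-sample test of mean difference; returns (t statistic, p value).

    ``welch`` is the unequal-variance t-test.  ``moderated`` shrinks the
    pooled sample variance toward ``prior_var`` with ``prior_df`` prior
    degrees of freedom (the limma-style empirical-Bayes contrast; for whole
    tables use :func:`moderated_t_table`, which estimates the prior across
    features).

    Degenerate inputs follow fixed conventions: zero variance in both groups
    with equal means gives (0, 1); zero variance with unequal means gives a
    zero p-value (infinite separation).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 replicates per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if mode == "welch":
        if va == 0 and vb == 0:
            if diff == 0:
                return 0.0, 1.0
            return math.copysign(math.inf, diff), 0.0
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if mode == "moderated":
        df_resid = len(a) + len(b) - 2
        s2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df_resid
        pv = s2 if prior_var is None else prior_var
        s2_post = (prior_df * pv + df_resid * s2) / (prior_df + df_resid)
        if s2_post == 0:
            if diff == 0:
                return 0.0, 1.0
            return math.copysign(math.inf, diff), 0.0
        se = math.sqrt(s2_post * (1 / len(a) + 1 / len(b)))
        t = diff / se
        df_total = df_resid + prior_df
        p = 2 * scipy.stats.t.sf(abs(t), df_total)
        return float(t), float(p)
    raise ValueError(f"unknown test mode {mode!r}")


def moderated_t_table(
    a: np.ndarray, b: np.ndarray, prior_df: float = DEFAULT_PRIOR_DF
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized moderated t over a feature table.

    ``a`` and ``b`` are (n_features, n_replicates) arrays.  The prior
    variance is the mean of the per-feature pooled sample variances — a
    deliberately simple plug-in for the empirical-Bayes prior.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df_resid = na + nb - 2
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df_resid
    prior_var = float(s2.mean()) if len(s2) else 0.0
    s2_post = (prior_df * prior_var + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_post * (1 / na + 1 / nb))
    diff = a.mean(axis=1) - b.mean(axis=1)
    t = np.divide(diff, se, out=np.full_like(diff, np.inf), where=se > 0)
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff < 0)] = -np.inf
    p = 2 * scipy.stats.t.sf(np.abs(t), df_resid + prior_df)
    p[np.isinf(t)] = 0.0
    p[(se == 0) & (diff == 0)] = 1.0
    return t, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# records and table readers


@dataclass
class ExpressionRecord:
    gene_id: str
    fpkm_mature: tuple[float, ...]
    fpkm_immature: tuple[float, ...]
    log2fc: float
    p_value: float | None
    q_value: float | None
    external_stats: bool = False


@dataclass
class ProteinRecord:
    protein_id: str
    gene_id: str
    log2ratio_mature: tuple[float, ...]
    log2ratio_immature: tuple[float, ...]
    log2fc: float
    p_value: float | None
    q_value: float | None
    external_stats: bool = False


@dataclass
class MetaboliteRecord:
    metabolite_id: str
    conc_mature: tuple[float, ...]
    conc_immature: tuple[float, ...]
    fold_change: float  # linear scale, mature / immature
    p_value: float | None
    q_value: float | None
    external_stats: bool = False


def _load_tsv(path, id_column: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={id_column: str})
    if id_column not in df.columns:
        raise SchemaError(f"{path}: missing required column {id_column}")
    dup = df[id_column][df[id_column].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate {id_column} values: {sorted(set(dup))}")
    return df

def _replicate_columns(df: pd.DataFrame, prefix: str) -> tuple[list[str], list[str]]:
    pat = re.compile(rf"^{prefix}_({CONDITION_A}|{CONDITION_B})_(\d+)$")
    cols_a, cols_b = [], []
    for c in df.columns:
        m = pat.match(c)
        if m:
            (cols_a if m.group(1) == CONDITION_A else cols_b).append(c)
    key = lambda c: int(c.rsplit("_", 1)[1])
    return sorted(cols_a, key=key), sorted(cols_b, key=key)


def _stats_from_table(
    df: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    log_scale: bool,
    pseudocount: float,
    test: str,
    prior_df: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log2fc, p, q) per row from replicate columns.

    ``log_scale`` marks data already on log2 scale (isobaric ratios): fold
    change is a difference of means, the test runs on the values as given.
    For linear-scale data (FPKM, concentrations) the fold change is a ratio
    of means with ``pseudocount``, and the test runs on log2(x + pseudocount)
    to respect the multiplicative noise of abundance measurements.
    """
    a = df[cols_a].to_numpy(dtype=float)
    b = df[cols_b].to_numpy(dtype=float)
    if log_scale:
        lfc = a.mean(axis=1) - b.mean(axis=1)
        ta, tb = a, b
    else:
        if np.any(a < 0) or np.any(b < 0):
            raise SchemaError("abundances must be non-negative")
        if pseudocount == 0 and (np.any(a == 0) or np.any(b == 0)):
            raise UndefinedValueError(
                "zero abundance with zero pseudocount: fold change undefined"
            )
        lfc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
        ta, tb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if test == "moderated":
        _, p = moderated_t_table(ta, tb, prior_df=prior_df)
    else:
        p = np.empty(len(df))
        for i in range(len(df)):
            _, p[i] = two_group_test(ta[i], tb[i], mode="welch")
    q = bh_adjust(p)
    return lfc, p, q


def _external_stats(df: pd.DataFrame, path) -> tuple[np.ndarray, list, list]:
    if "log2fc" not in df.columns and "fold_change" not in df.columns:
        raise SchemaError(
            f"{path}: need replicate columns or a precomputed log2fc/fold_change column"
        )
    p = df["p_value"].tolist() if "p_value" in df.columns else [None] * len(df)
    if "q_value" in df.columns:
        q = df["q_value"].tolist()
    elif "p_value" in df.columns:
        q = list(bh_adjust(df["p_value"].to_numpy(dtype=float)))
    else:
        q = [None] * len(df)
    for pi, qi in zip(p, q):
        if pi is not None and qi is not None and qi < pi - 1e-12:
            raise SchemaError(f"{path}: adjusted p smaller than raw p")
    fc = df["log2fc"] if "log2fc" in df.columns else df["fold_change"]
    return fc.to_numpy(dtype=float), p, q


def read_expression_table(
    path, pseudocount: float = DEFAULT_FPKM_PSEUDOCOUNT, test: str = "welch"
) -> list[ExpressionRecord]:
    """Read a transcript table: ``gene_id`` plus ``fpkm_<cond>_<rep>`` columns.

    Precomputed ``log2fc``/``p_value``/``q_value`` columns (a DE-caller
    export) are trusted as-is and flagged ``external_stats``; otherwise the
    contrast is computed from the replicates and BH-adjusted in-table.
    """
    df = _load_tsv(path, "gene_id")
    cols_a, cols_b = _replicate_columns(df, "fpkm")
    if cols_a and cols_b and "log2fc" not in df.columns:
        if np.any(df[cols_a + cols_b].to_numpy(dtype=float) < 0):
            raise SchemaError(f"{path}: FPKM values must be non-negative")
        lfc, p, q = _stats_from_table(df, cols_a, cols_b, False, pseudocount, test, DEFAULT_PRIOR_DF)
        external = False
    else:
        lfc, p, q = _external_stats(df, path)
        external = True
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            ExpressionRecord(
                gene_id=normalize_gene_id(getattr(row, "gene_id")),
                fpkm_mature=tuple(float(getattr(row, c)) for c in cols_a),
                fpkm_immature=tuple(float(getattr(row, c)) for c in cols_b),
                log2fc=float(lfc[i]),
                p_value=None if p[i] is None else float(p[i]),
                q_value=None if q[i] is None else float(q[i]),
                external_stats=external,
            )
        )
    return records


def read_protein_table(path, test: str = "moderated") -> list[ProteinRecord]:
    """Read a protein table: ``protein_id``, ``gene_id``, ``log2ratio_<cond>_<rep>``.

    Ratios are already log2 (isobaric channel over pooled reference), so the
    fold change is a difference of group means and no pseudocount applies.
    The default test is the moderated contrast, matching how low-replicate
    proteome panels are usually analyzed.
    """
    df = _load_tsv(path, "protein_id")
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column gene_id")
    cols_a, cols_b = _replicate_columns(df, "log2ratio")
    if cols_a and cols_b and "log2fc" not in df.columns:
        lfc, p, q = _stats_from_table(df, cols_a, cols_b, True, 0.0, test, DEFAULT_PRIOR_DF)
        external = False
    else:
        lfc, p, q = _external_stats(df, path)
        external = True
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            ProteinRecord(
                protein_id=str(getattr(row, "protein_id")),
                gene_id=normalize_gene_id(str(getattr(row, "gene_id"))),
                log2ratio_mature=tuple(float(getattr(row, c)) for c in cols_a),
                log2ratio_immature=tuple(float(getattr(row, c)) for c in cols_b),
                log2fc=float(lfc[i]),
                p_value=None if p[i] is None else float(p[i]),
                q_value=None if q[i] is None else float(q[i]),
                external_stats=external,
            )
        )
    return records


def read_metabolite_table(path, test: str = "welch") -> list[MetaboliteRecord]:
    """Read a metabolite table: ``metabolite_id`` plus ``conc_<cond>_<rep>``.

    Fold change is reported on the linear scale (concentration ratio,
    mature over immature), as metabolite panels conventionally are; the test
    runs on log2 concentrations.
    """
    df = _load_tsv(path, "metabolite_id")
    cols_a, cols_b = _replicate_columns(df, "conc")
    if cols_a and cols_b and "fold_change" not in df.columns:
        lfc, p, q = _stats_from_table(df, cols_a, cols_b, False, 0.0, test, DEFAULT_PRIOR_DF)
        fc = np.exp2(lfc)
        external = False
    else:
        fc, p, q = _external_stats(df, path)
        if np.any(fc <= 0):
            raise SchemaError(f"{path}: fold_change must be positive")
        external = True
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            MetaboliteRecord(
                metabolite_id=str(getattr(row, "metabolite_id")),
                conc_mature=tuple(float(getattr(row, c)) for c in cols_a),
                conc_immature=tuple(float(getattr(row, c)) for c in cols_b),
                fold_change=float(fc[i]),
                p_value=None if p[i] is None else float(p[i]),
                q_value=None if q[i] is None else float(q[i]),
                external_stats=external,
            )
        )
    return records
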