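"""SNP-phenotype association scan (single-marker GLM with Bonferroni).

Each marker is tested by ordinary least squares of a binary phenotype on
the 0/1 genotype code -- the single-factor general linear model of the
classic TASSEL scan.  R^2 is the model sum of squares over the total and
the p-value comes from F(1, n-2).  Markers are pre-filtered to minor
allele frequency strictly above a threshold (default 0.25), and raw
p-values are Bonferroni-corrected by the number of markers tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .seq_model import SNPMatrix

__all__ = ["AssocResult", "filter_markers", "glm_assoc", "scan", "encode_phenotype"]


@dataclass
class AssocResult:
    """Per-marker association result."""

    position: int
    r2: float
    p_raw: float
    p_bonferroni: float
    n_used: int
    minor_allele: str = ""
    defined: bool = True


def filter_markers(snps: SNPMatrix, maf_threshold: float = 0.25) -> SNPMatrix:
    """Retain markers with MAF strictly greater than the threshold."""
    if not (0.0 <= maf_threshold <= 0.5):
        raise ValueError("maf_threshold must be in [0, 0.5]")
    keep = snps.maf > maf_threshold
    return SNPMatrix(
        names=list(snps.names),
        positions=snps.positions[keep],
        codes=snps.codes[:, keep],
        maf=snps.maf[keep],
        major=[m for m, k in zip(snps.major, keep) if k],
        minor=[m for m, k in zip(snps.minor, keep) if k],
    )


def glm_assoc(genotype: np.ndarray, phenotype: np.ndarray) -> tuple[float, float, int]:
    """OLS of phenotype on one genotype column: (R^2, raw P, n used).

    Genotype codes {0, 1}, missing as -1 or NaN; pairs with either value
    missing are dropped.  Constant genotype or phenotype -> (nan, nan, n).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(g) & np.isfinite(y) & (g >= 0) & (y >= 0)
    g, y = g[ok], y[ok]
    n = len(g)
    if n < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, n
    gc = g - g.mean()
    yc = y - y.mean()
    beta = float(gc @ yc) / float(gc @ gc)
    ss_tot = float(yc @ yc)
    ss_mod = beta * float(gc @ yc)
    r2 = ss_mod / ss_tot
    if r2 >= 1.0:
        return 1.0, 0.0, n
    F = (n - 2) * r2 / (1.0 - r2)
    p = float(f_dist.sf(F, 1, n - 2))
    return r2, p, n


def scan(snps: SNPMatrix, phenotype: np.ndarray) -> pd.DataFrame:
    """Association scan over all markers of a (filtered) SNP matrix.

    Returns one row per marker sorted by position, with raw and
    Bonferroni-corrected p-values (m = number of markers tested) and
    significance flags at corrected 0.05 and 0.01.
    """
    m = snps.codes.shape[1]
    records = []
    for j in range(m):
        try:
            r2, p, n_used = glm_assoc(snps.codes[:, j], phenotype)
        except ValueError:
            r2, p, n_used = math.nan, math.nan, 0
        records.append(
            {
                "position": int(snps.positions[j]),
                "r2": r2,
                "p_raw": p,
                "n_used": n_used,
                "minor_allele": snps.minor[j] if snps.minor else "",
                "maf": float(snps.maf[j]),
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df):
        df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * m)
        df["sig_05"] = df["p_bonferroni"] < 0.05
        df["sig_01"] = df["p_bonferroni"] < 0.01
        df = df.sort_values("position", kind="stable").reset_index(drop=True)
    return df


def encode_phenotype(
    classes: pd.Series | dict, contrast: str = "avr2"
) -> pd.Series:
    """Binary contrast from the four phenotype classes.

    Classes: I = protein not accumulated (pseudogenes; always excluded),
    II = insensitive to the AVR2 inhibitor, III = inhibited with attenuated
    HR, IV = inhibited with strong HR.  Contrast ``avr2`` codes II vs
    {III, IV}; contrast ``hr`` codes III vs IV.  Excluded alleles get NaN.
    """
    ser = pd.Series(classes, dtype=str)
    if contrast == "avr2":
        mapping = {"II": 1.0, "III": 0.0, "IV": 0.0}
    elif contrast == "hr":
        mapping = {"III": 1.0, "IV": 0.0}
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return ser.map(lambda c: mapping.get(c, math.nan))
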