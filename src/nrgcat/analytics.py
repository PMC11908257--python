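"""Catalog- and profile-level statistics.

Accumulation curves, threshold detection counts, compositional
co-occurrence (CLR + thresholded Pearson, a stated concretization of the
SECOM-style linear correlation with a hard threshold), and single-feature
ROC AUC.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .model import Rank


def accumulation_curve(
    matrix: pd.DataFrame, n_orders: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean cumulative distinct-feature counts over random sample orders.

    ``matrix`` is samples x features (boolean or abundance; nonzero means
    present).  Returns a DataFrame (position, mean, sd) where position i is
    the i-th sample added (1-based).  Each per-order curve is monotone
    nondecreasing by construction.
    """
    if matrix.shape[0] < 1:
        raise ParameterError("accumulation_curve requires at least one sample")
    present = matrix.to_numpy() != 0
    n_samples = present.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_orders, n_samples), dtype=float)
    for o in range(n_orders):
        order = rng.permutation(n_samples)
        seen = np.zeros(present.shape[1], dtype=bool)
        for i, s in enumerate(order):
            seen |= present[s]
            curves[o, i] = seen.sum()
    return pd.DataFrame(
        {
            "position": np.arange(1, n_samples + 1),
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=0),
        }
    )


def count_species_over_threshold(
    comp, taxa: Iterable, threshold: float = 0.01
) -> int:
    """Count the listed taxa with share strictly above ``threshold``.

    ``comp`` may be a CompositionProfile or a plain name->share mapping.
    """
    names = set(taxa)
    if hasattr(comp, "shares"):
        shares = {
            t.name: s
            for t, s in comp.shares.items()
            if t.rank in (Rank.SPECIES, Rank.GENUS)
        }
    else:
        shares = dict(comp)
    return sum(1 for name in names if shares.get(name, 0.0) > threshold)


def clr_transform(
    matrix: pd.DataFrame, pseudocount: Optional[float] = None
) -> pd.DataFrame:
    """Centered log-ratio transform per sample (rows).

    The default pseudocount is half the smallest nonzero value of each row.
    """
    values = matrix.to_numpy(dtype=float).copy()
    out = np.empty_like(values)
    for i, row in enumerate(values):
        if pseudocount is None:
            nonzero = row[row > 0]
            pc = nonzero.min() / 2.0 if nonzero.size else 1e-9
        else:
            pc = pseudocount
        logs = np.log(row + pc)
        out[i] = logs - logs.mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cooccurrence(
    abundance: pd.DataFrame,
    hard_threshold: float = 0.3,
    alpha: float = 0.001,
    pseudocount: Optional[float] = None,
) -> tuple:
    """Pairwise thresholded Pearson correlation on CLR abundances.

    For each taxon pair, Pearson r is computed over the samples where either
    taxon is detected (raw abundance > 0); coefficients with |r| below
    ``hard_threshold`` or with p >= ``alpha`` are set to 0.  Returns
    ``(r matrix, flags matrix)`` where flags marks undefined coefficients
    (constant columns / too few samples), reported as 0.
    """
    if abundance.shape[0] < 10:
        raise ParameterError("cooccurrence requires at least 10 samples")
    if abundance.shape[1] < 2:
        raise ParameterError("cooccurrence requires at least 2 taxa")
    taxa = list(abundance.columns)
    raw = abundance.to_numpy(dtype=float)
    clr = clr_transform(abundance, pseudocount).to_numpy()
    n = len(taxa)
    r = np.eye(n)
    flags = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            mask = (raw[:, i] > 0) | (raw[:, j] > 0)
            x, y = clr[mask, i], clr[mask, j]
            constant = (
                np.ptp(raw[mask, i]) == 0 or np.ptp(raw[mask, j]) == 0
                or np.ptp(x) == 0 or np.ptp(y) == 0
            )
            if mask.sum() < 3 or constant:
                flags[i, j] = flags[j, i] = True
                continue
            rij, p = stats.pearsonr(x, y)
            if abs(rij) < hard_threshold or p >= alpha:
                rij = 0.0
            r[i, j] = r[j, i] = rij
    return (
        pd.DataFrame(r, index=taxa, columns=taxa),
        pd.DataFrame(flags, index=taxa, columns=taxa),
    )


def auc_single_feature(values, labels) -> float:
    """AUC = P(value_pos > value_neg) + 0.5 P(tie) over all +/- pairs.

    Computed via average ranks, which is exactly the pair-enumeration
    definition including tie handling.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("auc_single_feature requires both classes")
    ranks = stats.rankdata(values)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )
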