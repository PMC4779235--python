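"""Structural alerts from continuous activity data (e.g. pIC50, Ki).

For each candidate substructure S the training activities are split into
distribution A (compounds containing S) and distribution B (the rest).
Normality of A and B is assessed with the Shapiro-Wilk test; if both
pass at the gate level, a two-tailed independent-samples t test compares
them, otherwise the two-sample Kolmogorov-Smirnov test is used.  The
signed effect size mean(A) - mean(B), in activity units, says whether
the substructure increases or decreases activity; significance alone is
not a judgement of practical relevance, so the effect size is always
reported alongside the P value.

Unlike the categorical scan there is no smallest-radius suppression:
every distinct qualifying substructure of the test set is evaluated
exactly once, in first-encounter order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .alerts_categorical import bonferroni_correct
from .molecule_io import (
    MoleculeSet,
    SubstructureIndex,
    as_molecule_list,
    enumerate_atom_environments,
    extract_substructure_information,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitDistributions",
    "ContinuousAlert",
    "ContinuousAlertMiner",
    "split_by_substructure",
    "test_substructure_effect",
    "derive_alerts_continuous",
    "export_results",
    "results_to_frame",
]

# Shapiro-Wilk is unreliable above ~5000 points; larger samples are
# subsampled with a fixed seed so the gate stays deterministic.
_SHAPIRO_CAP = 5000


@dataclass
class SplitDistributions:
    """Activity values of compounds with (A) and without (B) a substructure."""

    a: np.ndarray
    b: np.ndarray


@dataclass
class ContinuousAlert:
    identifier: int
    smiles: str
    radius: int
    n_a: int
    ratio: float
    p_value: float
    test_used: str  # "t" | "ks"
    effect_size: float  # mean(A) - mean(B), activity units
    p_value_corrected: float = np.nan
    significant: bool = False

    @property
    def direction(self) -> str:
        return "increases" if self.effect_size > 0 else "decreases"


def split_by_substructure(index: SubstructureIndex, activities,
                          identifier: int) -> SplitDistributions:
    """Partition the training activities by presence of one substructure."""
    if identifier not in index:
        raise KeyError(f"unknown substructure identifier: {identifier}")
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (index.n,):
        raise ValueError("activities not parallel to the training set")
    members = np.zeros(index.n, dtype=bool)
    members[list(index.entries[identifier])] = True
    return SplitDistributions(a=activities[members], b=activities[~members])


def _is_normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        return False  # zero variance: degenerate, route to KS
    if sample.size > _SHAPIRO_CAP:
        rng = np.random.default_rng(0)
        sample = rng.choice(sample, size=_SHAPIRO_CAP, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(sample).pvalue > alpha


def test_substructure_effect(split: SplitDistributions, alpha: float = 0.05,
                             welch: bool = False
                             ) -> tuple[float, str, float]:
    """Compare distributions A and B; returns (p_value, test_used, effect).

    Both samples must have >= 3 values (Shapiro-Wilk minimum); smaller
    splits are a skip condition for the caller, not a statistical
    result.  ``welch=False`` uses the pooled-variance t test.
    """
    a, b = np.asarray(split.a, float), np.asarray(split.b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both samples need >= 3 values for the normality "
                         "gate")
    effect = float(a.mean() - b.mean())
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        return p, "t", effect
    p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
    return p, "ks", effect


class ContinuousAlertMiner(BaseEstimator):
    """Derive substructures associated with continuous activity.

    Parameters
    ----------
    radii:
        Bond radii of the environments considered (required).
    min_support:
        Minimum number of training compounds with the substructure
        (|A|); inclusive gate. Required; no default.
    min_ratio:
        Minimum |A| / n (training-set size); inclusive. Required.
    alpha:
        Level for both the Shapiro-Wilk gate and the main test.
        Default 0.05.
    bonferroni:
        Multiply P values by the number of computed tests. Default True.
    welch:
        Use the unequal-variance t test instead of the pooled one.
        Default False.

    Fitted attributes
    -----------------
    index_ : SubstructureIndex of the training set
    activities_ : float vector parallel to the training molecules
    """

    def __init__(self, radii: Iterable[int] | None = None,
                 min_support: int | None = None,
                 min_ratio: float | None = None, alpha: float = 0.05,
                 bonferroni: bool = True, welch: bool = False):
        self.radii = radii
        self.min_support = min_support
        self.min_ratio = min_ratio
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.welch = welch

    def _validate(self) -> tuple[int, ...]:
        if self.radii is None:
            raise ValueError("radii is required and has no default")
        radii = tuple(sorted(set(int(r) for r in self.radii)))
        if not radii:
            raise ValueError("radii must be non-empty")
        if self.min_support is None or self.min_ratio is None:
            raise ValueError("min_support and min_ratio are required and "
                             "have no defaults")
        if not 0 <= float(self.min_ratio) <= 1:
            raise ValueError("min_ratio must lie in [0, 1]")
        if not 0 < float(self.alpha) < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return radii

    def fit(self, X, y=None):
        radii = self._validate()
        if y is None:
            if not (isinstance(X, MoleculeSet)
                    and X.activity_kind == "continuous"):
                raise ValueError("y is required unless X is a MoleculeSet "
                                 "with continuous activities attached")
            y = X.activities
        mols = as_molecule_list(X)
        activities = np.asarray(y, dtype=float)
        if activities.shape != (len(mols),):
            raise ValueError("activity vector not parallel to the molecules")
        self.index_ = extract_substructure_information(mols, radii)
        self.activities_ = activities
        self.n_features_in_ = 1
        return self

    def derive(self, X) -> list[ContinuousAlert]:
        """Evaluate every qualifying distinct substructure of a test set."""
        check_is_fitted(self, "index_")
        radii = self._validate()
        if frozenset(radii) != self.index_.radii_allowed:
            raise ValueError("radii differ from the ones the index was "
                             "built with")
        mols = as_molecule_list(X)
        index = self.index_
        min_support = int(self.min_support)
        min_ratio = float(self.min_ratio)
        alpha = float(self.alpha)

        seen: set[int] = set()
        results: list[ContinuousAlert] = []
        for t, mol in enumerate(mols):
            for env in enumerate_atom_environments(mol, radii,
                                                   molecule_index=t):
                identifier = env.identifier
                if identifier in seen:
                    continue
                seen.add(identifier)
                if identifier not in index:
                    continue
                n_a = index.n_s(identifier)
                if n_a < min_support or n_a / index.n < min_ratio:
                    continue
                split = split_by_substructure(index, self.activities_,
                                              identifier)
                if split.a.size < 3 or split.b.size < 3:
                    logger.info("substructure %d skipped: split too small "
                                "for the normality gate (|A|=%d, |B|=%d)",
                                identifier, split.a.size, split.b.size)
                    continue
                p, test_used, effect = test_substructure_effect(
                    split, alpha=alpha, welch=self.welch)
                results.append(ContinuousAlert(
                    identifier=identifier,
                    smiles=index.smiles_of[identifier],
                    radius=env.radius, n_a=n_a, ratio=n_a / index.n,
                    p_value=p, test_used=test_used, effect_size=effect))

        raw = [r.p_value for r in results]
        corrected = bonferroni_correct(raw) if self.bonferroni else np.asarray(raw)
        for res, pc in zip(results, corrected):
            res.p_value_corrected = float(pc)
            res.significant = bool(pc < alpha)
        results.sort(key=lambda r: (r.p_value_corrected, r.p_value,
                                    r.identifier))
        self.results_ = results
        return results

    def fit_derive(self, X_train, y, X_test) -> list[ContinuousAlert]:
        return self.fit(X_train, y).derive(X_test)


def derive_alerts_continuous(
    test_set,
    train_set,
    y=None,
    *,
    radii: Iterable[int],
    min_support: int,
    min_ratio: float,
    alpha: float = 0.05,
    bonferroni: bool = True,
    welch: bool = False,
) -> list[ContinuousAlert]:
    """One-call wrapper over :class:`ContinuousAlertMiner`."""
    miner = ContinuousAlertMiner(radii=radii, min_support=min_support,
                                 min_ratio=min_ratio, alpha=alpha,
                                 bonferroni=bonferroni, welch=welch)
    return miner.fit_derive(train_set, y, test_set)


def results_to_frame(results: Sequence[ContinuousAlert]) -> pd.DataFrame:
    columns = ["identifier", "smiles", "radius", "n_A", "ratio", "test_used",
               "p_value", "p_value_corrected", "significant", "effect_size",
               "direction"]
    rows = [
        (r.identifier, r.smiles, r.radius, r.n_a, r.ratio, r.test_used,
         r.p_value, r.p_value_corrected, r.significant, r.effect_size,
         r.direction)
        for r in results
    ]
    return pd.DataFrame(rows, columns=columns)


def export_results(results: Sequence, path, format: str = "csv") -> None:
    """Write categorical or continuous results to CSV or xlsx.

    CSV output is byte-stable for identical input.
    """
    from .alerts_categorical import CategoricalAlert
    from .alerts_categorical import results_to_frame as _cat_frame

    if results and isinstance(results[0], CategoricalAlert):
        frame = _cat_frame(results)
    else:
        frame = results_to_frame(list(results))
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError("format must be 'csv' or 'xlsx'")
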