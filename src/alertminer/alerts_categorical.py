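"""Structural alerts from dichotomous (active/inactive) activity data.

For a training set of ``n`` compounds of which ``m`` are active, a
substructure S contained in ``n_S`` training compounds, ``m_S_act`` of
them active, is scored by the upper binomial tail

    P = sum_{i = m_S_act}^{n_S} C(n_S, i) (m/n)^i (1 - m/n)^(n_S - i)

i.e. the probability of observing at least ``m_S_act`` actives among the
``n_S`` carriers if activity were independent of S.  A small P marks S
as enriched among actives (only enrichment is tested; the statistic is a
one-sided upper tail).

The scan walks the substructures of a *test* set smallest radius first
at each root atom: gates on training support (``n_S``) and on the
active-carrier frequency (``m_S_act / n_S``) decide whether a P value is
computed at all, and once a substructure is flagged significant, larger
environments rooted at the same atom are suppressed and the substructure
is never reconsidered.  The Bonferroni correction multiplies the P
values by the number of P values actually computed in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .molecule_io import (
    AtomEnvironment,  # noqa: F401  (re-exported: the scan's unit of work)
    MoleculeSet,
    SubstructureIndex,
    as_molecule_list,
    enumerate_atom_environments,
    extract_substructure_information,
)

__all__ = [
    "AtomEnvironment",
    "LabeledIndex",
    "CategoricalAlert",
    "CategoricalAlertMiner",
    "binomial_tail_pvalue",
    "bonferroni_correct",
    "derive_alerts_categorical",
    "results_to_frame",
]


def binomial_tail_pvalue(n: int, m: int, n_s: int, m_s_act: int) -> float:
    """Upper-tail binomial probability P(X >= m_s_act), X ~ Bin(n_s, m/n).

    ``n``: training-set size; ``m``: actives in the training set;
    ``n_s``: training compounds containing the substructure;
    ``m_s_act``: active training compounds containing it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= m <= n:
        raise ValueError("m must satisfy 0 <= m <= n")
    if not 0 <= m_s_act <= n_s:
        raise ValueError("m_s_act must satisfy 0 <= m_s_act <= n_s")
    if m_s_act == 0:
        return 1.0  # full sum over the mass function
    # sf(k) = P(X > k), so P(X >= m_s_act) = sf(m_s_act - 1)
    return float(stats.binom.sf(m_s_act - 1, n_s, m / n))


def bonferroni_correct(p_values: Sequence[float]) -> np.ndarray:
    """Multiply each P value by the number of tests, clamped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


@dataclass
class LabeledIndex:
    """A substructure index plus the binary activity of each training molecule."""

    index: SubstructureIndex
    active_mask: np.ndarray

    def __post_init__(self) -> None:
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.active_mask.shape != (self.index.n,):
            raise ValueError("activity mask not parallel to the training set")

    @property
    def n(self) -> int:
        return self.index.n

    @property
    def m(self) -> int:
        return int(self.active_mask.sum())

    def counts(self, identifier: int) -> tuple[int, int]:
        """(n_S, m_S_act) for one substructure."""
        members = self.index.entries[identifier]
        n_s = len(members)
        m_s_act = int(self.active_mask[list(members)].sum())
        return n_s, m_s_act


@dataclass
class CategoricalAlert:
    identifier: int
    smiles: str
    radius: int
    n_s: int
    m_s_act: int
    p_value: float
    p_value_corrected: float = np.nan
    significant: bool = False
    example: tuple[int, int] = (0, 0)  # (test molecule index, root atom)

    @property
    def frequency(self) -> float:
        return self.m_s_act / self.n_s


class CategoricalAlertMiner(BaseEstimator):
    """Derive structural alerts from active/inactive training data.

    Parameters
    ----------
    radii:
        Bond radii of the environments considered (required; no default).
    min_support:
        Minimum ``n_S`` (training compounds with the substructure)
        required to compute a P value; inclusive. Default 5.
    min_frequency:
        Minimum ``m_S_act / n_S`` required to compute a P value;
        inclusive. Required; no default.
    alpha:
        Significance level. Default 0.05.
    bonferroni:
        Multiply P values by the number of computed tests. Default True.
    bonferroni_during_scan:
        When True, the in-scan suppression decision compares the raw P
        value against ``alpha`` divided by the running count of computed
        P values instead of plain ``alpha``.  Default False: suppression
        uses raw P < alpha and the final significance flag uses the
        post-scan corrected values.

    Fitted attributes
    -----------------
    labeled_index_ : LabeledIndex over the training set
    n_, m_ : training-set size and number of actives
    """

    def __init__(self, radii: Iterable[int] | None = None,
                 min_support: int = 5, min_frequency: float | None = None,
                 alpha: float = 0.05, bonferroni: bool = True,
                 bonferroni_during_scan: bool = False):
        self.radii = radii
        self.min_support = min_support
        self.min_frequency = min_frequency
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.bonferroni_during_scan = bonferroni_during_scan

    def _validate(self) -> tuple[int, ...]:
        if self.radii is None:
            raise ValueError("radii is required and has no default")
        radii = tuple(sorted(set(int(r) for r in self.radii)))
        if not radii:
            raise ValueError("radii must be non-empty")
        if self.min_frequency is None:
            raise ValueError("min_frequency is required and has no default")
        if not 0 <= float(self.min_frequency) <= 1:
            raise ValueError("min_frequency must lie in [0, 1]")
        if not 0 < float(self.alpha) < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.min_support) < 1:
            raise ValueError("min_support must be >= 1")
        return radii

    def fit(self, X, y=None):
        """Index the training molecules and their binary activities.

        ``X`` may be a MoleculeSet (with binary activities attached, in
        which case ``y`` may be omitted), a list of RDKit molecules or a
        list of SMILES; ``y`` is a parallel vector of active/inactive
        labels (bool, 0/1 or recognizable text labels).
        """
        radii = self._validate()
        if y is None:
            if not (isinstance(X, MoleculeSet) and X.activity_kind == "binary"):
                raise ValueError("y is required unless X is a MoleculeSet "
                                 "with binary activities attached")
            y = X.activities
        mols = as_molecule_list(X)
        mask = _as_binary_mask(y, len(mols))
        index = extract_substructure_information(mols, radii)
        self.labeled_index_ = LabeledIndex(index=index, active_mask=mask)
        self.n_ = self.labeled_index_.n
        self.m_ = self.labeled_index_.m
        self.n_features_in_ = 1
        return self

    def derive(self, X) -> list[CategoricalAlert]:
        """Scan a test set and return all evaluated substructures.

        Results carry raw and corrected P values and the significance
        flag; alerts come first, in ascending corrected P value.
        """
        check_is_fitted(self, "labeled_index_")
        radii = self._validate()
        if frozenset(radii) != self.labeled_index_.index.radii_allowed:
            raise ValueError("radii differ from the ones the index was "
                             "built with")
        mols = as_molecule_list(X)
        labeled = self.labeled_index_
        alpha = float(self.alpha)
        min_support = int(self.min_support)
        min_frequency = float(self.min_frequency)

        processed: set[int] = set()
        results: list[CategoricalAlert] = []
        flagged: set[int] = set()
        n_computed = 0
        for t, mol in enumerate(mols):
            by_root: dict[int, list] = {}
            for env in enumerate_atom_environments(mol, radii,
                                                   molecule_index=t):
                by_root.setdefault(env.root_atom, []).append(env)
            for root in sorted(by_root):
                for env in sorted(by_root[root], key=lambda e: e.radius):
                    identifier = env.identifier
                    if identifier in processed:
                        continue
                    if identifier not in labeled.index:
                        processed.add(identifier)
                        continue
                    n_s, m_s_act = labeled.counts(identifier)
                    # gates: support and active-carrier frequency (inclusive)
                    if n_s < min_support or m_s_act / n_s < min_frequency:
                        processed.add(identifier)
                        continue
                    p = binomial_tail_pvalue(labeled.n, labeled.m, n_s,
                                             m_s_act)
                    n_computed += 1
                    processed.add(identifier)
                    results.append(CategoricalAlert(
                        identifier=identifier,
                        smiles=labeled.index.smiles_of[identifier],
                        radius=env.radius, n_s=n_s, m_s_act=m_s_act,
                        p_value=p, example=(t, root)))
                    threshold = (alpha / n_computed
                                 if self.bonferroni_during_scan else alpha)
                    if p < threshold:
                        flagged.add(identifier)
                        break  # suppress larger radii rooted at this atom

        k = len(results)
        for res in results:
            res.p_value_corrected = (min(res.p_value * k, 1.0)
                                     if self.bonferroni else res.p_value)
            if self.bonferroni_during_scan:
                res.significant = res.identifier in flagged
            else:
                reference = (res.p_value_corrected if self.bonferroni
                             else res.p_value)
                res.significant = reference < alpha
        results.sort(key=lambda r: (not r.significant, r.p_value_corrected,
                                    r.p_value, r.identifier))
        self.results_ = results
        return results

    def fit_derive(self, X_train, y, X_test) -> list[CategoricalAlert]:
        return self.fit(X_train, y).derive(X_test)


def _as_binary_mask(y, n: int) -> np.ndarray:
    from .molecule_io import _normalize_binary_labels

    arr = np.asarray(y)
    if arr.shape != (n,):
        raise ValueError(f"activity vector length {arr.shape} does not match "
                         f"{n} molecules")
    if arr.dtype == bool:
        return arr
    if np.issubdtype(arr.dtype, np.number):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError("numeric binary labels must be 0/1")
        return arr.astype(bool)
    return _normalize_binary_labels(list(arr))


def derive_alerts_categorical(
    test_set,
    train_set,
    y=None,
    *,
    radii: Iterable[int],
    min_support: int = 5,
    min_frequency: float,
    alpha: float = 0.05,
    bonferroni: bool = True,
    bonferroni_during_scan: bool = False,
) -> list[CategoricalAlert]:
    """One-call wrapper over :class:`CategoricalAlertMiner`."""
    miner = CategoricalAlertMiner(
        radii=radii, min_support=min_support, min_frequency=min_frequency,
        alpha=alpha, bonferroni=bonferroni,
        bonferroni_during_scan=bonferroni_during_scan)
    return miner.fit_derive(train_set, y, test_set)


def results_to_frame(results: Sequence[CategoricalAlert]) -> pd.DataFrame:
    columns = ["identifier", "smiles", "radius", "n_S", "m_S_act",
               "frequency", "p_value", "p_value_corrected", "significant",
               "example_molecule", "example_atom"]
    rows = [
        (r.identifier, r.smiles, r.radius, r.n_s, r.m_s_act, r.frequency,
         r.p_value, r.p_value_corrected, r.significant, r.example[0],
         r.example[1])
        for r in results
    ]
    return pd.DataFrame(rows, columns=columns)
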