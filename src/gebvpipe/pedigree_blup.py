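"""Pedigree-based breeding values: relationship matrix and animal-model BLUP.

The traditional reference against which genomic predictions are judged:
an animal model ``y = 1*mu + Z*u + e`` with ``u ~ N(0, A*sigma2_a)`` where
A is the numerator relationship matrix from the pedigree.  Solutions come
from Henderson's mixed-model equations; A-inverse is built directly by
Henderson's rules with inbreeding taken from the tabular-method diagonal.
Variance components default to a user-supplied heritability; a
one-dimensional REML grid search is available when h2 is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import Pedigree, UNKNOWN


@dataclass
class EBVResult:
    ebv: pd.Series          # id -> estimated breeding value
    mean: float             # overall-mean fixed effect estimate
    h2: float
    variance_ratio: float   # (1 - h2) / h2 used in the MME


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Additive (numerator) relationship matrix by the tabular method.

    Requires parents-before-offspring ordering (enforced by ``Pedigree``).
    Diagonal is 1 + F_i; founders are assumed unrelated and non-inbred.
    """
    n = pedigree.n
    s_idx, d_idx = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        if s < 0:
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    return np.diag(relationship_matrix(pedigree)) - 1.0


def relationship_inverse(pedigree: Pedigree,
                         inbreeding: np.ndarray | None = None) -> np.ndarray:
    """A-inverse by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of individual i is
    ``0.5 - 0.25*(F_s + F_d)`` with both parents known, 1 for founders.
    """
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(pedigree)
    n = pedigree.n
    s_idx, d_idx = pedigree.parent_indices()
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        if s < 0:
            Ainv[i, i] += 1.0
            continue
        alpha = 1.0 / (0.5 - 0.25 * (inbreeding[s] + inbreeding[d]))
        Ainv[i, i] += alpha
        for p in (s, d):
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
        for p in (s, d):
            for q in (s, d):
                Ainv[p, q] += alpha / 4.0
    return Ainv


def _incidence(pedigree: Pedigree, ids: np.ndarray) -> np.ndarray:
    pos = pedigree.index_of
    Z = np.zeros((len(ids), pedigree.n))
    for r, i in enumerate(ids):
        Z[r, pos[int(i)]] = 1.0
    return Z


def solve_animal_model(phenotypes: pd.Series, pedigree: Pedigree,
                       h2: float = 0.5) -> EBVResult:
    """Single-trait animal model with the overall mean as the only fixed
    effect, solved through Henderson's mixed-model equations.

    ``phenotypes`` is indexed by individual id; individuals absent from it
    carry no record but still receive an EBV through their relatives.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    ids = np.asarray(phenotypes.index, dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("no phenotyped individuals")
    y = phenotypes.to_numpy(dtype=float)
    lam = (1.0 - h2) / h2
    n = pedigree.n
    Z = _incidence(pedigree, ids)
    Ainv = relationship_inverse(pedigree)
    # MME: [ n_rec  1'Z ; Z'1  Z'Z + Ainv*lam ] [mu; u] = [1'y ; Z'y]
    lhs = np.zeros((n + 1, n + 1))
    lhs[0, 0] = len(y)
    zt1 = Z.sum(axis=0)
    lhs[0, 1:] = zt1
    lhs[1:, 0] = zt1
    lhs[1:, 1:] = Z.T @ Z + Ainv * lam
    rhs = np.concatenate(([y.sum()], Z.T @ y))
    sol = np.linalg.solve(lhs, rhs)
    return EBVResult(
        ebv=pd.Series(sol[1:], index=pedigree.id, name="ebv"),
        mean=float(sol[0]), h2=h2, variance_ratio=lam,
    )


def reml_h2_grid(phenotypes: pd.Series, pedigree: Pedigree,
                 grid: np.ndarray | None = None) -> float:
    """Restricted-likelihood grid search for heritability.

    Profiles the total variance analytically; suitable for the moderate
    record counts of this pipeline, not a general REML replacement.
    """
    if grid is None:
        grid = np.linspace(0.05, 0.95, 19)
    ids = np.asarray(phenotypes.index, dtype=np.int64)
    y = phenotypes.to_numpy(dtype=float)
    A = relationship_matrix(pedigree)
    Z = _incidence(pedigree, ids)
    ZAZ = Z @ A @ Z.T
    nrec = len(y)
    X = np.ones((nrec, 1))
    best, best_ll = None, -np.inf
    for h2 in grid:
        V0 = h2 * ZAZ + (1.0 - h2) * np.eye(nrec)
        sign, logdet = np.linalg.slogdet(V0)
        Vi = np.linalg.inv(V0)
        XtViX = float((X.T @ Vi @ X).item())
        P = Vi - (Vi @ X @ X.T @ Vi) / XtViX
        q = float(y @ P @ y)
        s2 = q / (nrec - 1)
        ll = -0.5 * ((nrec - 1) * (1.0 + np.log(s2)) + logdet + np.log(XtViX))
        if ll > best_ll:
            best, best_ll = float(h2), ll
    return best


def write_ebv(result: EBVResult, path, trait: str = "trait") -> None:
    pd.DataFrame({"id": result.ebv.index, "ebv": result.ebv.to_numpy(),
                  "trait": trait}).to_csv(path, index=False)


def read_ebv(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["ebv"].to_numpy(), index=df["id"].to_numpy(), name="ebv")
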