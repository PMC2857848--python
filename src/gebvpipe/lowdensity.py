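"""Low-density SNP panel scenarios for GEBV prediction without retraining.

Marker effects are always estimated once, at full density, on the training
population.  Prediction-set individuals then get GEBV = X_m beta_m under
twelve panel scenarios crossing (i) how the genotyped subset is chosen —
evenly spaced across the genome (EVEN) or by largest absolute posterior
effect (SIG), (ii) its size m in {19, 38, 76}, and (iii) whether the
remaining markers are filled with pedigree-derived expected genotype codes
(the _GP variants, which use all effects) or simply dropped (which uses
only the subset's effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoprob import expected_code_matrix
from .simdata import GenotypeMatrix, MarkerMap

PANEL_SIZES = (19, 38, 76)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    selection: str              # "even" | "sig"
    m_genotyped: int
    use_genotype_probabilities: bool

    def __post_init__(self) -> None:
        if self.selection not in ("even", "sig"):
            raise ValueError("selection must be 'even' or 'sig'")
        if self.m_genotyped < 1:
            raise ValueError("m_genotyped must be >= 1")

    def total_markers(self, panel_size: int) -> int:
        return panel_size if self.use_genotype_probabilities else self.m_genotyped


@dataclass
class GEBVResult:
    gebv: pd.Series             # id -> genomic breeding value
    scenario: str
    method: str
    trait: str
    retrained: bool = False     # effects always come from full-density training

    def __post_init__(self) -> None:
        if self.retrained:
            raise ValueError("scenario GEBV must reuse full-density effects")


def scenario_catalogue() -> list[ScenarioSpec]:
    """The twelve standard scenarios: {EVEN, SIG} x {19, 38, 76} x {plain, GP}."""
    out = []
    for sel in ("even", "sig"):
        for gp in (False, True):
            for m in PANEL_SIZES:
                tag = "GP_" if gp else ""
                out.append(ScenarioSpec(f"{sel.upper()}_{tag}{m}", sel, m, gp))
    return out


def get_scenario(name: str) -> ScenarioSpec:
    for s in scenario_catalogue():
        if s.name == name.upper():
            return s
    raise KeyError(f"unknown scenario {name!r}")


def select_even(marker_map: MarkerMap, m: int,
                rule: str = "quantile") -> np.ndarray:
    """Indices of m markers spaced evenly across the genome.

    The default rule places targets at the quantile centres (i - 0.5)/m of
    cumulative map length and takes the nearest marker to each (ties to
    the lower index; a marker already taken steps to the next unused one).
    ``rule='stride'`` instead takes every (panel/m)-th marker by index.
    """
    M = marker_map.m
    if not (1 <= m <= M):
        raise ValueError("m must lie in [1, panel size]")
    if rule == "stride":
        return np.unique(((np.arange(m) + 0.5) * M / m).astype(int))
    if rule != "quantile":
        raise ValueError("rule must be 'quantile' or 'stride'")
    cum = marker_map.cumulative_positions()
    total = float(cum.max())
    chosen: list[int] = []
    used = np.zeros(M, dtype=bool)
    for i in range(m):
        target = (i + 0.5) / m * total
        dist = np.abs(cum - target)
        j = int(np.argmin(dist))  # argmin takes the lower index on ties
        while used[j]:
            j += 1
            if j >= M:  # fall back to the nearest unused below
                j = int(np.flatnonzero(~used)[-1])
                break
        used[j] = True
        chosen.append(j)
    return np.array(sorted(chosen), dtype=np.int64)


def select_largest_effects(beta_means: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest |posterior mean effect|, ties to the lower
    marker index, returned in ascending index order."""
    beta = np.asarray(beta_means, dtype=float)
    if not (1 <= m <= len(beta)):
        raise ValueError("m must lie in [1, panel size]")
    order = np.lexsort((np.arange(len(beta)), -np.abs(beta)))
    return np.array(sorted(order[:m]), dtype=np.int64)


def select_markers(spec: ScenarioSpec, marker_map: MarkerMap,
                   beta_means: np.ndarray | None = None) -> np.ndarray:
    if spec.selection == "even":
        return select_even(marker_map, spec.m_genotyped)
    if beta_means is None:
        raise ValueError("effect-based selection needs trained beta means")
    return select_largest_effects(beta_means, spec.m_genotyped)


def build_design(genotypes: GenotypeMatrix, probs: np.ndarray | None,
                 spec: ScenarioSpec, selected: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Scenario design matrix and the matching effect-column index.

    With genotype probabilities off, the design holds only the selected
    markers' observed codes (paired with the matching effect subset).
    With them on, all markers are present: observed codes in the selected
    columns, expected dosages P1 + 2*P2 everywhere else.
    """
    G = genotypes.codes
    if np.any(np.isnan(G[:, selected])):
        raise ValueError("selected panel markers must be observed in the "
                         "prediction set")
    if not spec.use_genotype_probabilities:
        return G[:, selected].copy(), np.asarray(selected, dtype=np.int64)
    if probs is None:
        raise ValueError("genotype probabilities required for a _GP scenario")
    if probs.shape[:2] != G.shape:
        raise ValueError("probability table shape does not match genotypes")
    X = expected_code_matrix(probs)
    X[:, selected] = G[:, selected]
    return X, np.arange(G.shape[1], dtype=np.int64)


def compute_gebv(X_m: np.ndarray, beta_m: np.ndarray,
                 ids: np.ndarray | None = None, scenario: str = "ALL",
                 method: str = "", trait: str = "") -> GEBVResult:
    """GEBV_i = sum_j X_m[i, j] * beta_j (no intercept; correlations and
    regressions downstream are location-invariant)."""
    X_m = np.asarray(X_m, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    if X_m.shape[1] != len(beta_m):
        raise ValueError("design columns must match effect vector length")
    g = X_m @ beta_m
    idx = np.asarray(ids) if ids is not None else np.arange(len(g))
    return GEBVResult(pd.Series(g, index=idx, name="gebv"),
                      scenario=scenario, method=method, trait=trait)


def scenario_gebv(spec: ScenarioSpec, genotypes: GenotypeMatrix,
                  beta_means: np.ndarray, marker_map: MarkerMap,
                  probs: np.ndarray | None = None, method: str = "",
                  trait: str = "") -> GEBVResult:
    """End-to-end scenario evaluation: select markers, build the design,
    multiply through the full-density posterior-mean effects."""
    selected = select_markers(spec, marker_map, beta_means)
    X_m, cols = build_design(genotypes, probs, spec, selected)
    return compute_gebv(X_m, np.asarray(beta_means)[cols], genotypes.ids,
                        scenario=spec.name, method=method, trait=trait)


def write_gebv(results: list[GEBVResult], path) -> None:
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "id": r.gebv.index, "scenario": r.scenario, "method": r.method,
            "trait": r.trait, "gebv": r.gebv.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gebv(path) -> pd.DataFrame:
    return pd.read_csv(path)
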