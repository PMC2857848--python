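"""Synthetic livestock populations for genomic-prediction pipelines.

Generates a two-generation full/half-sib population of the kind used in
genomic-selection method comparisons: a handful of sires mated to a larger
set of dams, a large offspring cohort of which only half is phenotyped,
SNP genotypes dropped through the pedigree with Haldane recombination, and
longitudinal growth phenotypes driven by a small number of additive QTL
acting on the Gompertz asymptote.  True breeding values are recorded so
that prediction accuracy can be measured against truth rather than only
against pedigree EBV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0  # parent code for founders in TSV files and arrays

DEFAULT_TIMEPOINTS = (0, 132, 265, 397, 530)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Pedigree records ordered parents-before-offspring.

    ``id`` are unique positive integers; ``sire``/``dam`` are 0 for unknown
    (founders).  ``generation`` is 0 for founders, 1 for their offspring, etc.
    """

    id: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        self.id = np.asarray(self.id, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.id)

    @property
    def index_of(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.id)}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per individual, -1 for unknown."""
        idx = self.index_of
        s = np.array([idx.get(int(p), -1) for p in self.sire], dtype=np.int64)
        d = np.array([idx.get(int(p), -1) for p in self.dam], dtype=np.int64)
        return s, d

    def validate(self) -> None:
        if len(set(self.id.tolist())) != self.n:
            raise ValueError("pedigree ids are not unique")
        if np.any(self.id <= 0):
            raise ValueError("pedigree ids must be positive")
        seen: set[int] = set()
        for i, s, d in zip(self.id, self.sire, self.dam):
            for p in (s, d):
                if p != UNKNOWN and int(p) not in seen:
                    raise ValueError(
                        f"parent {int(p)} of {int(i)} does not precede it"
                    )
            if (s == UNKNOWN) != (d == UNKNOWN):
                raise ValueError(f"individual {int(i)} has exactly one known parent")
            seen.add(int(i))

    def founders(self) -> np.ndarray:
        return self.id[self.sire == UNKNOWN]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.id, "sire": self.sire, "dam": self.dam,
             "generation": self.generation}
        )


@dataclass
class MarkerMap:
    """Marker genome coordinates: chromosome index and position in Morgan."""

    marker: list[str]
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.float64)
        if np.any(self.pos < 0):
            raise ValueError("map positions must be >= 0")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions decrease within chromosome {c}")

    @property
    def m(self) -> int:
        return len(self.marker)

    def chrom_blocks(self) -> list[np.ndarray]:
        """Marker indices per chromosome, in map order."""
        return [np.flatnonzero(self.chrom == c) for c in np.unique(self.chrom)]

    def cumulative_positions(self) -> np.ndarray:
        """Genome-wide coordinate: position plus the summed length of
        preceding chromosomes (length = max mapped position per chromosome)."""
        out = np.empty(self.m)
        offset = 0.0
        for block in self.chrom_blocks():
            out[block] = self.pos[block] + offset
            offset += float(self.pos[block].max())
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "chrom": self.chrom, "pos_morgan": self.pos}
        )


@dataclass
class GenotypeMatrix:
    """n x m genotype codes (copies of the reference allele, 0/1/2).

    Stored as float so missing entries can be NaN; fully observed matrices
    round-trip to integers.
    """

    ids: np.ndarray
    markers: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match ids/markers")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def complete(self) -> bool:
        return not np.any(np.isnan(self.codes))

    def subset_individuals(self, ids: np.ndarray) -> "GenotypeMatrix":
        pos = {int(i): k for k, i in enumerate(self.ids)}
        rows = np.array([pos[int(i)] for i in ids], dtype=np.int64)
        return GenotypeMatrix(np.asarray(ids), list(self.markers),
                              self.codes[rows].copy())


@dataclass
class TruthSet:
    """Simulated truth: QTL positions/effects and true breeding values."""

    qtl_index: np.ndarray          # marker indices carrying QTL
    qtl_effect: np.ndarray         # additive effect per QTL (asymptote units)
    tbv: pd.Series                 # id -> TBV (asymptote units)
    h2: float
    seed: int
    train_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    predict_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


@dataclass(frozen=True)
class GompertzParams:
    """Base growth curve y(t) = A * exp(-b * exp(-k * t))."""

    A: float = 100.0
    b: float = 3.0
    k: float = 0.01


# ---------------------------------------------------------------------------
# Simulation operations
# ---------------------------------------------------------------------------

def simulate_pedigree(n_sires: int, n_dams: int, n_offspring: int,
                      seed: int = 0) -> Pedigree:
    """Two-generation mating design: each dam mated to exactly one sire.

    Dams are split as evenly as possible over sires and offspring as evenly
    as possible over dams, producing full-sib families nested in half-sib
    sire groups.  Deterministic given the arguments (the seed is reserved
    for future randomised designs).
    """
    if min(n_sires, n_dams, n_offspring) < 1:
        raise ValueError("counts must be >= 1")
    n_f = n_sires + n_dams
    ids = np.arange(1, n_f + n_offspring + 1, dtype=np.int64)
    sire = np.zeros(n_f + n_offspring, dtype=np.int64)
    dam = np.zeros(n_f + n_offspring, dtype=np.int64)
    gen = np.zeros(n_f + n_offspring, dtype=np.int64)
    gen[n_f:] = 1
    dam_sire = 1 + (np.arange(n_dams) * n_sires) // n_dams  # even split
    off_dam = (np.arange(n_offspring) * n_dams) // n_offspring
    for j in range(n_offspring):
        d = off_dam[j]
        sire[n_f + j] = dam_sire[d]
        dam[n_f + j] = n_sires + d + 1
    return Pedigree(ids, sire, dam, gen)


def default_marker_map(n_markers: int = 453, n_chrom: int = 5,
                       chrom_length: float = 1.0) -> MarkerMap:
    """Approximately equally spaced markers across equal-length chromosomes."""
    base, extra = divmod(n_markers, n_chrom)
    names, chroms, pos = [], [], []
    for c in range(n_chrom):
        k = base + (1 if c < extra else 0)
        p = (np.arange(k) + 0.5) / k * chrom_length
        pos.append(p)
        chroms.append(np.full(k, c + 1))
        names += [f"M{c + 1}_{j + 1}" for j in range(k)]
    return MarkerMap(names, np.concatenate(chroms), np.concatenate(pos))


def _gamete(hap: np.ndarray, marker_map: MarkerMap,
            rng: np.random.Generator) -> np.ndarray:
    """One meiosis: recombination between adjacent markers per Haldane
    (r = (1 - exp(-2d))/2), chromosomes independent, no interference."""
    m = hap.shape[0]
    out = np.empty(m, dtype=hap.dtype)
    for block in marker_map.chrom_blocks():
        d = np.diff(marker_map.pos[block])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        cross = rng.random(len(d)) < r
        strand = (rng.integers(2) + np.concatenate(([0], np.cumsum(cross)))) % 2
        out[block] = hap[block, strand]
    return out


def simulate_genomes(pedigree: Pedigree, marker_map: MarkerMap,
                     founder_freqs: float | np.ndarray = 0.5,
                     seed: int = 0) -> GenotypeMatrix:
    """Gene-drop simulation of SNP genotypes through the pedigree.

    Founders draw Hardy-Weinberg genotypes at the supplied reference-allele
    frequencies (linkage equilibrium); gametes recombine per Haldane's map
    function.  All genotypes are fully observed and Mendelian-consistent.
    """
    m = marker_map.m
    p = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (m,))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("founder allele frequencies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = pedigree.n
    hap = np.empty((n, m, 2), dtype=np.int8)
    s_idx, d_idx = pedigree.parent_indices()
    for i in range(n):
        if s_idx[i] < 0:
            hap[i, :, 0] = rng.random(m) < p
            hap[i, :, 1] = rng.random(m) < p
        else:
            hap[i, :, 0] = _gamete(hap[s_idx[i]], marker_map, rng)
            hap[i, :, 1] = _gamete(hap[d_idx[i]], marker_map, rng)
    codes = hap.sum(axis=2).astype(np.float64)
    return GenotypeMatrix(pedigree.id.copy(), list(marker_map.marker), codes)


def gompertz(t: np.ndarray | float, A: float, b: float, k: float):
    return A * np.exp(-b * np.exp(-k * np.asarray(t, dtype=float)))


def simulate_phenotypes(pedigree: Pedigree, genotypes: GenotypeMatrix,
                        n_qtl: int = 10, h2: float = 0.5,
                        timepoints: tuple = DEFAULT_TIMEPOINTS,
                        growth_base: GompertzParams = GompertzParams(),
                        genetic_cv: float = 0.10,
                        effect_shape: float = 0.4,
                        seed: int = 0) -> tuple[pd.DataFrame, TruthSet]:
    """Longitudinal growth phenotypes with additive QTL on the asymptote.

    A random subset of ``n_qtl`` markers receives additive effects drawn
    from a reflected gamma (``effect_shape`` small => few large effects),
    rescaled so the TBV standard deviation equals ``genetic_cv`` times the
    base asymptote.  Individual i grows along a Gompertz curve with
    asymptote ``A + TBV_i``; i.i.d. Gaussian noise per time point is sized
    so heritability at the last time point equals ``h2``.  Only the
    designated training half of the offspring (alternating within family)
    receives phenotypes; TBV are recorded for everyone.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    if n_qtl > genotypes.m:
        raise ValueError("more QTL than markers")
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    rng = np.random.default_rng(seed)
    X = genotypes.codes
    if n_qtl > 0:
        qtl = np.sort(rng.choice(genotypes.m, size=n_qtl, replace=False))
        raw = rng.gamma(effect_shape, 1.0, size=n_qtl)
        raw *= rng.choice([-1.0, 1.0], size=n_qtl)
        tbv_raw = X[:, qtl] @ raw
        sd = tbv_raw.std()
        scale = (genetic_cv * growth_base.A / sd) if sd > 0 else 0.0
        effects = raw * scale
    else:
        qtl = np.empty(0, dtype=np.int64)
        effects = np.empty(0)
    tbv = X[:, qtl] @ effects if n_qtl else np.zeros(genotypes.n)

    # growth-curve multiplier at each time point; genetic signal at time t
    # is TBV * g(t), so residual sd is set from the last-time-point h2
    g = np.exp(-growth_base.b * np.exp(-growth_base.k * np.asarray(timepoints, float)))
    var_g_last = np.var(tbv) * g[-1] ** 2
    if h2 < 1.0 and var_g_last > 0:
        sigma_e = float(np.sqrt(var_g_last * (1.0 - h2) / h2))
    elif h2 < 1.0:
        sigma_e = genetic_cv * growth_base.A * g[-1]  # pure-noise trait
    else:
        sigma_e = 0.0

    offspring = pedigree.id[pedigree.generation > 0]
    # alternate within family so train/predict sets both span all families
    fam = {}
    train_mask = np.zeros(len(offspring), dtype=bool)
    sire_of = dict(zip(pedigree.id.tolist(), pedigree.sire.tolist()))
    dam_of = dict(zip(pedigree.id.tolist(), pedigree.dam.tolist()))
    for k_i, ind in enumerate(offspring):
        key = (sire_of[int(ind)], dam_of[int(ind)])
        c = fam.get(key, 0)
        train_mask[k_i] = (c % 2 == 0)
        fam[key] = c + 1
    train_ids = offspring[train_mask]
    predict_ids = offspring[~train_mask]

    pos = {int(i): k for k, i in enumerate(genotypes.ids)}
    rows = np.array([pos[int(i)] for i in train_ids])
    asym = growth_base.A + tbv[rows]
    mean_curve = asym[:, None] * g[None, :]
    noise = rng.normal(0.0, sigma_e, size=mean_curve.shape) if sigma_e > 0 else 0.0
    values = mean_curve + noise
    pheno = pd.DataFrame(values, columns=[f"t{int(t)}" for t in timepoints])
    pheno.insert(0, "id", train_ids)

    truth = TruthSet(
        qtl_index=qtl, qtl_effect=effects,
        tbv=pd.Series(tbv, index=genotypes.ids, name="tbv"),
        h2=h2, seed=seed, train_ids=train_ids, predict_ids=predict_ids,
    )
    return pheno, truth


def check_mendelian(pedigree: Pedigree, genotypes: GenotypeMatrix) -> bool:
    """True iff every offspring genotype is reachable from parental gametes."""
    s_idx, d_idx = pedigree.parent_indices()
    G = genotypes.codes
    for i in range(pedigree.n):
        if s_idx[i] < 0:
            continue
        for j in range(genotypes.m):
            g, gs, gd = G[i, j], G[s_idx[i], j], G[d_idx[i], j]
            if np.isnan(g) or np.isnan(gs) or np.isnan(gd):
                continue
            ok = {(a + b) for a in _gamete_alleles(gs) for b in _gamete_alleles(gd)}
            if g not in ok:
                return False
    return True


def _gamete_alleles(g: float) -> tuple:
    return {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}[float(g)]


# ---------------------------------------------------------------------------
# File I/O (plain-text TSV/CSV; NA marks missing)
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    return Pedigree(df["id"], df["sire"], df["dam"], df["generation"])


def write_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    return MarkerMap(df["marker"].tolist(), df["chrom"], df["pos_morgan"])


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.codes, columns=geno.markers)
    df.insert(0, "id", geno.ids)
    out = df.copy()
    for c in geno.markers:  # integer codes with NA for missing
        out[c] = df[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    markers = [c for c in df.columns if c != "id"]
    return GenotypeMatrix(df["id"].to_numpy(), markers,
                          df[markers].to_numpy(dtype=float))


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: TruthSet, tbv_path, qtl_path) -> None:
    pd.DataFrame({"id": truth.tbv.index, "tbv": truth.tbv.to_numpy()}).to_csv(
        tbv_path, index=False)
    pd.DataFrame({"qtl_index": truth.qtl_index,
                  "effect": truth.qtl_effect}).to_csv(qtl_path, index=False)


def read_truth(tbv_path, qtl_path, h2: float = float("nan"),
               seed: int = -1) -> TruthSet:
    tbv = pd.read_csv(tbv_path)
    qtl = pd.read_csv(qtl_path)
    return TruthSet(qtl["qtl_index"].to_numpy(np.int64),
                    qtl["effect"].to_numpy(float),
                    pd.Series(tbv["tbv"].to_numpy(), index=tbv["id"].to_numpy(),
                              name="tbv"),
                    h2=h2, seed=seed)
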