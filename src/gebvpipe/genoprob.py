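"""Single-locus genotype probabilities by iterative peeling.

For a marker with genotypes observed on only part of a pedigree,
segregation analysis propagates information both down (anterior: parents
and, through them, full sibs) and up (posterior: mates and offspring)
until the three-class genotype probabilities stabilise.  Founders carry a
Hardy-Weinberg prior at a supplied (or estimated) allele frequency.  The
resulting probabilities feed the expected-genotype coding
``P(het) + 2*P(hom)`` used when computing genomic breeding values from a
low-density panel: markers with a real genotype keep their 0/1/2 code and
the rest are filled with the expected code.

Single-marker only: no linkage, haplotyping or LD-based imputation.
Iterative peeling is exact on loop-free pedigrees; with inbreeding loops
it is an approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, Pedigree

_TOL = 1e-8
_MAX_ROUNDS = 50


class MendelianError(ValueError):
    """Observed genotypes are impossible under Mendelian transmission."""


def _transmission() -> np.ndarray:
    """T[gs, gd, gc] = P(child genotype gc | parent genotypes gs, gd)."""
    gam = np.array([0.0, 0.5, 1.0])  # P(transmit reference allele | genotype)
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            ps, pd_ = gam[gs], gam[gd]
            T[gs, gd, 0] = (1 - ps) * (1 - pd_)
            T[gs, gd, 1] = ps * (1 - pd_) + (1 - ps) * pd_
            T[gs, gd, 2] = ps * pd_
    return T


_T = _transmission()


def hardy_weinberg_prior(p: float) -> np.ndarray:
    """Genotype-class prior (P0, P1, P2) at reference-allele frequency p."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def _penetrance(observed: np.ndarray) -> np.ndarray:
    pen = np.ones((len(observed), 3))
    for i, g in enumerate(observed):
        if not np.isnan(g):
            pen[i] = 0.0
            pen[i, int(g)] = 1.0
    return pen


def single_locus_probabilities(pedigree: Pedigree, observed: np.ndarray,
                               allele_freq: float, tol: float = _TOL,
                               max_rounds: int = _MAX_ROUNDS) -> np.ndarray:
    """Three-class genotype probabilities for every pedigree member.

    ``observed`` is one genotype column in pedigree order (NaN = missing).
    Returns an (n, 3) array of (P0, P1, P2); rows of observed individuals
    are exact point masses.  Raises :class:`MendelianError`, naming the
    offending trio, when the observed data are inconsistent.
    """
    if not (0.0 < allele_freq < 1.0):
        raise ValueError("allele_freq must lie in (0, 1)")
    observed = np.asarray(observed, dtype=float)
    n = pedigree.n
    if len(observed) != n:
        raise ValueError("observed column length must match pedigree size")
    s_idx, d_idx = pedigree.parent_indices()
    pen = _penetrance(observed)
    prior = hardy_weinberg_prior(allele_freq)

    # nuclear families: (sire_row, dam_row) -> child rows
    families: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        if s_idx[i] >= 0:
            families.setdefault((s_idx[i], d_idx[i]), []).append(i)
    fam_keys = list(families.keys())
    fams_of_parent: dict[int, list[int]] = {}
    for fk, (s, d) in enumerate(fam_keys):
        fams_of_parent.setdefault(s, []).append(fk)
        fams_of_parent.setdefault(d, []).append(fk)

    ant = np.tile(prior, (n, 1))
    for i in range(n):  # initial anterior of non-founders: flat
        if s_idx[i] >= 0:
            ant[i] = np.ones(3) / 3.0
    post = np.ones((len(fam_keys), n, 3))  # post[fk, parent] contributions

    def upward(i: int, exclude_fam: int) -> np.ndarray:
        """pen * posterior product, excluding one family's contribution."""
        w = pen[i].copy()
        for fk in fams_of_parent.get(i, ()):
            if fk != exclude_fam:
                w = w * post[fk, i]
        return w

    def current_probs() -> np.ndarray:
        out = np.empty((n, 3))
        for i in range(n):
            w = ant[i] * upward(i, -1)
            tot = w.sum()
            if tot <= 0.0:
                raise MendelianError(
                    f"genotype configuration impossible for individual "
                    f"{int(pedigree.id[i])} (sire {int(pedigree.sire[i])}, "
                    f"dam {int(pedigree.dam[i])})")
            out[i] = w / tot
        return out

    probs = current_probs()
    for _ in range(max_rounds):
        for fk, (s, d) in enumerate(fam_keys):
            children = families[fam_keys[fk]]
            ws = ant[s] * upward(s, fk)
            wd = ant[d] * upward(d, fk)
            if ws.sum() <= 0 or wd.sum() <= 0:
                raise MendelianError(
                    f"genotype configuration impossible in family of sire "
                    f"{int(pedigree.id[s])} and dam {int(pedigree.id[d])}")
            # child_sums[c, gs, gd] = sum_gc T[gs,gd,gc] * upward_info_c[gc]
            nc = len(children)
            child_sums = np.empty((nc, 3, 3))
            up_info = np.empty((nc, 3))
            for ci, c in enumerate(children):
                up_info[ci] = upward(c, -1)  # children are never parents in
                # their own family, so no exclusion needed here
                child_sums[ci] = np.einsum("sdc,c->sd", _T, up_info[ci])
            # prefix/suffix products allow exclusion without division
            prefix = np.ones((nc + 1, 3, 3))
            for ci in range(nc):
                prefix[ci + 1] = prefix[ci] * child_sums[ci]
            suffix = np.ones((nc + 1, 3, 3))
            for ci in range(nc - 1, -1, -1):
                suffix[ci] = suffix[ci + 1] * child_sums[ci]
            prod_all = prefix[nc]
            # posterior contributions to the parents
            ps = prod_all @ wd           # sum_gd wd[gd] prod_all[gs, gd]
            pd_ = prod_all.T @ ws
            post[fk, s] = _normalize(ps)
            post[fk, d] = _normalize(pd_)
            # anterior of each child (excluding its own upward info)
            for ci, c in enumerate(children):
                excl = prefix[ci] * suffix[ci + 1]
                joint = ws[:, None] * wd[None, :] * excl
                ant[c] = _normalize(np.einsum("sdc,sd->c", _T, joint))
        new_probs = current_probs()
        delta = float(np.max(np.abs(new_probs - probs)))
        probs = new_probs
        if delta < tol:
            break
    # exact point masses for observed individuals
    for i in range(n):
        if not np.isnan(observed[i]):
            probs[i] = 0.0
            probs[i, int(observed[i])] = 1.0
    return probs


def _normalize(w: np.ndarray) -> np.ndarray:
    tot = w.sum()
    return w / tot if tot > 0 else np.ones_like(w) / len(w)


def estimate_allele_freq(observed: np.ndarray,
                         founder_mask: np.ndarray | None = None) -> float:
    """Reference-allele frequency from observed codes.

    Counts alleles over genotyped founders when at least 10 are available
    (the natural base-population estimate), otherwise over all genotyped
    individuals; clamped to [0.01, 0.99] so Hardy-Weinberg priors stay
    proper.
    """
    observed = np.asarray(observed, dtype=float)
    seen = ~np.isnan(observed)
    if not np.any(seen):
        raise ValueError("no observed genotypes")
    use = seen
    if founder_mask is not None:
        fm = seen & np.asarray(founder_mask, dtype=bool)
        if fm.sum() >= 10:
            use = fm
    p = float(observed[use].sum() / (2.0 * use.sum()))
    return min(max(p, 0.01), 0.99)


def expected_genotype_code(p1: float, p2: float) -> float:
    """Expected allele dosage P(het) + 2*P(hom) in [0, 2]."""
    if p1 < 0 or p2 < 0 or p1 + p2 > 1.0 + 1e-9:
        raise ValueError("invalid genotype probabilities")
    return p1 + 2.0 * p2


def genotype_probability_table(pedigree: Pedigree, genotypes: GenotypeMatrix,
                               allele_freqs: np.ndarray | None = None,
                               markers: list[str] | None = None
                               ) -> np.ndarray:
    """Probabilities for every individual x marker: (n, m, 3) array.

    ``genotypes`` rows must follow pedigree order; missing codes (NaN) are
    inferred by peeling, observed ones become point masses.  Allele
    frequencies default to per-marker estimates from the observed codes.
    """
    pos = {mk: j for j, mk in enumerate(genotypes.markers)}
    cols = [pos[mk] for mk in markers] if markers is not None else range(genotypes.m)
    founder_mask = pedigree.sire == 0
    out = np.empty((genotypes.n, len(list(cols)), 3))
    for k, j in enumerate(cols):
        col = genotypes.codes[:, j]
        p = (allele_freqs[j] if allele_freqs is not None
             else estimate_allele_freq(col, founder_mask))
        out[:, k, :] = single_locus_probabilities(pedigree, col, p)
    return out


def expected_code_matrix(probs: np.ndarray) -> np.ndarray:
    """Expected dosage matrix from an (n, m, 3) probability array."""
    return probs[:, :, 1] + 2.0 * probs[:, :, 2]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_probabilities(probs: np.ndarray, ids: np.ndarray,
                        markers: list[str], path) -> None:
    n, m, _ = probs.shape
    df = pd.DataFrame({
        "id": np.repeat(np.asarray(ids), m),
        "marker": np.tile(np.asarray(markers, dtype=object), n),
        "P0": probs[:, :, 0].ravel(),
        "P1": probs[:, :, 1].ravel(),
        "P2": probs[:, :, 2].ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def read_probabilities(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].unique()
    markers = df["marker"].unique().tolist()
    n, m = len(ids), len(markers)
    probs = df[["P0", "P1", "P2"]].to_numpy().reshape(n, m, 3)
    return probs, np.asarray(ids, dtype=np.int64), markers


def write_expected_codes(codes: np.ndarray, ids: np.ndarray,
                         markers: list[str], path) -> None:
    df = pd.DataFrame(codes, columns=markers)
    df.insert(0, "id", np.asarray(ids))
    df.to_csv(path, sep="\t", index=False)
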