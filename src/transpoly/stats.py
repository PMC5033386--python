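"""Diversity, selection and saturation statistics on allele alignments.

Implements the per-species summary machinery: nucleotide diversity (overall
and per synonymous/nonsynonymous site), the codon-based Z-test for positive
selection (modified Nei-Gojobori counts, bootstrap variance over codon
columns), Tajima's D, and an entropy-based substitution-saturation index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import AlleleAlignment
from .codon import SaturationError, _diff_table, _site_table, codon_indices
from .distances import distance_matrix, estimate_R


# ---------------------------------------------------------------------------
# per-codon count tensors shared by diversity and Z-test


def _codon_count_arrays(
    seqs: list[str], R: float, frame_offset: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(n_pairs, n_codons) arrays of nd, sd, N-sites, S-sites for all
    unordered pairs, pair index in lexicographic (i<j) order."""
    idx = [codon_indices(s, frame_offset) for s in seqs]
    sites = _site_table(R)
    diffs = _diff_table()
    n = len(seqs)
    n_codons = idx[0].shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ND = np.zeros((len(pairs), n_codons))
    SD = np.zeros_like(ND)
    NS = np.zeros_like(ND)
    SS = np.zeros_like(ND)
    for k, (i, j) in enumerate(pairs):
        a, b = idx[i], idx[j]
        ok = (a >= 0) & (b >= 0)
        ND[k] = np.where(ok, diffs[a, b, 0], 0.0)
        SD[k] = np.where(ok, diffs[a, b, 1], 0.0)
        SS[k] = np.where(ok, 0.5 * (sites[a, 0] + sites[b, 0]), 0.0)
        NS[k] = np.where(ok, 0.5 * (sites[a, 1] + sites[b, 1]), 0.0)
    return ND, SD, NS, SS


def _jc(p: np.ndarray) -> np.ndarray:
    """Vectorised Jukes-Cantor correction; NaN where saturated."""
    arg = 1.0 - 4.0 * np.asarray(p, dtype=float) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)


def _partition_columns(aln: AlleleAlignment, partition: str) -> np.ndarray:
    n_codons = aln.n_codons
    if partition == "full":
        return np.arange(n_codons)
    pbr = np.array(sorted(c for c in aln.pbr_codons if c < n_codons), dtype=int)
    if partition == "pbr":
        return pbr
    if partition == "non_pbr":
        return np.setdiff1d(np.arange(n_codons), pbr)
    raise ValueError(f"unknown partition {partition!r}")


# ---------------------------------------------------------------------------
# diversity


def nucleotide_diversity(
    aln: AlleleAlignment,
    mode: str = "overall",
    R: float | None = None,
    return_details: bool = False,
):
    """Mean pairwise diversity.

    mode 'overall': mean p-distance (pi); 'dS'/'dN': mean pairwise
    synonymous/nonsynonymous distance per respective site (modified
    Nei-Gojobori + Jukes-Cantor).  Saturated pairs are excluded and counted.
    """
    if len(aln) < 2:
        raise ValueError("need >= 2 sequences")
    if mode == "overall":
        D = distance_matrix(aln.seqs, model="p")
        iu = np.triu_indices(len(aln), k=1)
        vals = D[iu]
    elif mode in ("dS", "dN"):
        if R is None:
            R = estimate_R(aln.seqs)
        ND, SD, NS, SS = _codon_count_arrays(aln.seqs, R, aln.frame_offset)
        if mode == "dS":
            vals = _jc(SD.sum(axis=1) / SS.sum(axis=1))
        else:
            vals = _jc(ND.sum(axis=1) / NS.sum(axis=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    excluded = int(np.isnan(vals).sum())
    pi = float(np.nanmean(vals)) if excluded < vals.size else float("nan")
    if return_details:
        return pi, {"n_pairs": int(vals.size), "excluded_saturated": excluded}
    return pi


# ---------------------------------------------------------------------------
# codon Z-test


@dataclass(frozen=True)
class ZTestResult:
    z: float | None
    p: float | None
    mean_dn: float | None
    mean_ds: float | None
    applicable: bool
    reason: str = ""


def codon_z_test(
    aln: AlleleAlignment,
    partition: str = "full",
    boot_reps: int = 1000,
    R: float | None = None,
    seed: int | None = None,
) -> ZTestResult:
    """One-tailed codon Z-test for positive selection (H1: dN > dS).

    Z = (mean dN - mean dS) / SE, means over all sequence pairs, SE from
    bootstrap resampling of codon columns within the chosen partition.
    """
    if boot_reps < 100:
        raise ValueError("boot_reps must be >= 100")
    if len(aln) < 2:
        raise ValueError("need >= 2 sequences")
    if R is None:
        R = estimate_R(aln.seqs)
    cols = _partition_columns(aln, partition)
    if cols.size == 0:
        raise ValueError(f"empty partition {partition!r}")
    ND, SD, NS, SS = (a[:, cols] for a in _codon_count_arrays(aln.seqs, R, aln.frame_offset))
    if ND.sum() + SD.sum() == 0:
        return ZTestResult(None, None, None, None, False, "monomorphic alignment")

    def pair_means(col_idx: np.ndarray) -> tuple[float, float]:
        dn = _jc(ND[:, col_idx].sum(axis=1) / np.maximum(NS[:, col_idx].sum(axis=1), 1e-12))
        ds = _jc(SD[:, col_idx].sum(axis=1) / np.maximum(SS[:, col_idx].sum(axis=1), 1e-12))
        return float(np.nanmean(dn)), float(np.nanmean(ds))

    mean_dn, mean_ds = pair_means(np.arange(cols.size))
    if not (np.isfinite(mean_dn) and np.isfinite(mean_ds)):
        return ZTestResult(None, None, mean_dn, mean_ds, False, "saturation")

    rng = np.random.default_rng(seed)
    diffs = np.empty(boot_reps)
    for b in range(boot_reps):
        ci = rng.integers(0, cols.size, size=cols.size)
        bdn, bds = pair_means(ci)
        diffs[b] = bdn - bds
    se = float(np.nanstd(diffs, ddof=1))
    if se == 0 or not np.isfinite(se):
        return ZTestResult(None, None, mean_dn, mean_ds, False, "zero bootstrap variance")
    z = (mean_dn - mean_ds) / se
    p = float(sps.norm.sf(z))
    return ZTestResult(float(z), p, mean_dn, mean_ds, True)


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(aln: AlleleAlignment):
    """Standard Tajima (1989) D from segregating sites and mean pairwise
    differences; returns None (not applicable) when no sites segregate."""
    n = len(aln)
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    from .distances import encode

    mat = np.vstack([encode(s) for s in aln.seqs])
    valid = (mat >= 0).all(axis=0)
    mat = mat[:, valid]
    seg = (mat != mat[0]).any(axis=0)
    S = int(seg.sum())
    if S == 0:
        return None
    # mean pairwise differences
    k = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            k += float((mat[i] != mat[j]).sum())
            npairs += 1
    k /= npairs
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((k - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# saturation index


def saturation_test(
    aln: AlleleAlignment, reps: int = 200, seed: int | None = None
) -> tuple[float, float, float]:
    """Entropy-based index of substitution saturation.

    Iss is the mean per-site entropy of the alignment relative to the mean
    site entropy of fully saturated (uniform-random) alignments of the same
    dimensions, the latter estimated by Monte Carlo (``reps`` simulated
    alignments).  Returns (Iss, Iss_c, p) where Iss_c is the mean saturated
    index and p is the one-tailed one-sample t-test p-value for Iss < Iss_c.
    """
    if len(aln) < 4:
        raise ValueError("saturation test needs >= 4 sequences")
    if aln.length < 4:
        raise ValueError("alignment shorter than 4 sites")
    from .distances import encode

    mat = np.vstack([encode(s) for s in aln.seqs])
    n, L = mat.shape

    def site_entropies(m: np.ndarray) -> np.ndarray:
        ents = np.empty(m.shape[1])
        for j in range(m.shape[1]):
            col = m[:, j]
            col = col[col >= 0]
            if col.size == 0:
                ents[j] = 0.0
                continue
            counts = np.bincount(col, minlength=4).astype(float)
            f = counts[counts > 0] / col.size
            ents[j] = float(-(f * np.log2(f)).sum())
        return ents

    obs = site_entropies(mat)
    rng = np.random.default_rng(seed)
    sat_means = np.empty(reps)
    for r in range(reps):
        sat_means[r] = site_entropies(rng.integers(0, 4, size=(n, L))).mean()
    h_full = float(sat_means.mean())
    iss = float(obs.mean() / h_full) if h_full > 0 else 0.0
    iss_c = float(sat_means.mean() / h_full)  # = 1 by construction
    # one-sample t-test of per-site entropy ratios against the saturated mean
    ratios = obs / h_full
    t, p_two = sps.ttest_1samp(ratios, iss_c)
    p = p_two / 2.0 if t < 0 else 1.0 - p_two / 2.0
    return iss, iss_c, float(p)


# ---------------------------------------------------------------------------
# per-species summary table


def diversity_report(
    species_alignments: dict[str, AlleleAlignment],
    individual_counts: dict[str, list[int]] | None = None,
    R: float | None = None,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One row per species: sample size, variant counts, pi, pi_dS, pi_dN,
    dN/dS (1 decimal, matching conventional reporting precision), Z-test
    p-values for the full fragment and the PBR partition, and Tajima's D.

    ``individual_counts`` maps species -> per-individual allele counts (for
    the n and min-max range columns); omitted columns are left NA.
    """
    rows = []
    for k, (sp, aln) in enumerate(sorted(species_alignments.items())):
        if len(aln) < 2:
            raise ValueError(f"species {sp}: need >= 2 alleles")
        sub_seed = None if seed is None else seed + 1000 * k
        pi = nucleotide_diversity(aln, "overall")
        pi_ds = nucleotide_diversity(aln, "dS", R=R)
        pi_dn = nucleotide_diversity(aln, "dN", R=R)
        ratio = pi_dn / pi_ds if pi_ds > 0 else float("inf")
        z_full = codon_z_test(aln, "full", boot_reps=boot_reps, R=R, seed=sub_seed)
        z_pbr = codon_z_test(aln, "pbr", boot_reps=boot_reps, R=R, seed=sub_seed)
        try:
            td = tajimas_d(aln)
        except ValueError:
            td = None
        counts = individual_counts.get(sp) if individual_counts else None
        rows.append(
            {
                "species": sp,
                "n": len(counts) if counts else pd.NA,
                "variants_total": len(set(aln.seqs)),
                "variants_individual": f"{min(counts)}-{max(counts)}" if counts else pd.NA,
                "pi": round(pi, 3),
                "pi_dS": round(pi_ds, 3),
                "pi_dN": round(pi_dn, 3),
                "dn_ds": round(ratio, 1),
                "p_z_full": z_full.p,
                "p_z_pbr": z_pbr.p,
                "tajima_d": round(td, 3) if td is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "nucleotide_diversity",
    "codon_z_test",
    "ZTestResult",
    "tajimas_d",
    "saturation_test",
    "diversity_report",
    "SaturationError",
]
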