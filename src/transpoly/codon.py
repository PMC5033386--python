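"""Codon-level substitution counting: modified Nei-Gojobori dN/dS.

The modified Nei-Gojobori method weights transitional versus transversional
changes by a ratio ``R`` when classifying each codon position as a synonymous
or nonsynonymous "site"; the observed synonymous/nonsynonymous differences
between two codons are counted by averaging over every minimal substitution
pathway, exactly as in the unmodified method.  Both proportions are then
corrected for multiple hits with the Jukes-Cantor formula.

Conventions
-----------
* Mutations that would create a stop codon are excluded from site counting
  (the remaining changes at that position are renormalised so the position
  still contributes one site in total), and substitution pathways that pass
  through a stop codon are dropped from the pathway average.
* Sequences are read in-frame after an optional offset; a trailing partial
  codon is ignored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

BASES = "TCAG"

# standard genetic code, codon -> one-letter amino acid ('*' = stop)
GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(BASES, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate an in-frame nucleotide string; trailing remainder dropped."""
    s = seq[frame_offset:].upper()
    n = len(s) // 3
    return "".join(GENETIC_CODE.get(s[3 * i : 3 * i + 3], "X") for i in range(n))


def has_internal_stop(seq: str, frame_offset: int = 0) -> bool:
    aa = translate(seq, frame_offset)
    return "*" in aa


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class CodonSites:
    """Synonymous/nonsynonymous site counts for one codon."""

    syn: float
    nonsyn: float


@lru_cache(maxsize=None)
def codon_sites(codon: str, R: float = 1.0) -> CodonSites:
    """Modified Nei-Gojobori site counts for a single sense codon.

    Each of the three positions contributes one site, partitioned into a
    synonymous fraction: the weight-share of the single-nucleotide changes at
    that position that are synonymous, with transitions weighted ``R`` and
    transversions 1, and stop-creating changes excluded before normalising.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa0 = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        w_syn = 0.0
        w_tot = 0.0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            w = R if is_transition(codon[pos], b) else 1.0
            w_tot += w
            if GENETIC_CODE[alt] == aa0:
                w_syn += w
        if w_tot > 0:
            syn += w_syn / w_tot
    return CodonSites(syn=syn, nonsyn=3.0 - syn)


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) difference counts between two sense codons.

    Averaged over all minimal substitution pathways; pathways through stop
    codons are excluded.  If every pathway passes through a stop, changes are
    classified position-by-position against the direct amino-acid comparison
    (degenerate case; does not occur between observed stop-free sequences
    under the no-stop evolution model, but kept total-preserving).
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("stop codon in codon_differences")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)
    nd_tot = 0.0
    sd_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            nd_tot += nd
            sd_tot += sd
            n_paths += 1
    if n_paths == 0:
        # all pathways blocked by stops: fall back to per-position classification
        aa_same = GENETIC_CODE[c1] == GENETIC_CODE[c2]
        k = len(diff_pos)
        return (0.0, float(k)) if aa_same else (float(k), 0.0)
    return (nd_tot / n_paths, sd_tot / n_paths)


# ---------------------------------------------------------------------------
# vectorised lookup tables (built lazily, keyed by R for the site table)


@lru_cache(maxsize=8)
def _site_table(R: float) -> np.ndarray:
    """(n_sense, 2) array of (syn, nonsyn) sites per sense codon."""
    out = np.empty((len(SENSE_CODONS), 2))
    for i, c in enumerate(SENSE_CODONS):
        s = codon_sites(c, R)
        out[i] = (s.syn, s.nonsyn)
    return out


@lru_cache(maxsize=1)
def _diff_table() -> np.ndarray:
    """(n_sense, n_sense, 2) array of (nd, sd) pathway-averaged differences."""
    n = len(SENSE_CODONS)
    out = np.zeros((n, n, 2))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i < j:
                nd, sd = codon_differences(c1, c2)
                out[i, j] = (nd, sd)
                out[j, i] = (nd, sd)
    return out


def codons_of(seq: str, frame_offset: int = 0) -> list[str]:
    s = seq[frame_offset:].upper()
    return [s[3 * i : 3 * i + 3] for i in range(len(s) // 3)]


def codon_indices(seq: str, frame_offset: int = 0) -> np.ndarray:
    """Sense-codon index per codon; raises on internal stop codons."""
    idx = []
    for k, c in enumerate(codons_of(seq, frame_offset)):
        if c in STOP_CODONS:
            raise ValueError(f"premature stop codon {c} at codon {k}")
        try:
            idx.append(CODON_INDEX[c])
        except KeyError:
            idx.append(-1)  # ambiguous codon (contains N): excluded pairwise
    return np.asarray(idx, dtype=np.intp)


@dataclass(frozen=True)
class DnDsResult:
    """Pairwise modified Nei-Gojobori result."""

    dN: float
    dS: float
    N_sites: float
    S_sites: float
    nd: float
    sd: float
    pN: float
    pS: float


def _jc_correct(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"Jukes-Cantor log argument {arg:.4f} <= 0 (p={p:.4f})")
    return -0.75 * np.log(arg)


class SaturationError(ValueError):
    """Distance undefined: observed divergence at or beyond model saturation."""


def per_codon_counts(
    s1: str, s2: str, R: float = 1.0, frame_offset: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon-column (nd, sd, N, S) arrays for a sequence pair.

    Site counts are the mean of the two sequences' codons.  Columns where
    either codon is ambiguous are zeroed (pairwise deletion).
    """
    i1 = codon_indices(s1, frame_offset)
    i2 = codon_indices(s2, frame_offset)
    if i1.shape != i2.shape:
        raise ValueError("sequences have different codon counts")
    ok = (i1 >= 0) & (i2 >= 0)
    sites = _site_table(R)
    diffs = _diff_table()
    nd = np.where(ok, diffs[i1, i2, 0], 0.0)
    sd = np.where(ok, diffs[i1, i2, 1], 0.0)
    S = np.where(ok, 0.5 * (sites[i1, 0] + sites[i2, 0]), 0.0)
    N = np.where(ok, 0.5 * (sites[i1, 1] + sites[i2, 1]), 0.0)
    return nd, sd, N, S


def pairwise_dn_ds(s1: str, s2: str, R: float = 1.0, frame_offset: int = 0) -> DnDsResult:
    """Modified Nei-Gojobori dN and dS with Jukes-Cantor correction.

    Raises :class:`SaturationError` when either proportion reaches the
    Jukes-Cantor domain boundary (p >= 3/4), and ``ValueError`` on premature
    stop codons.
    """
    nd, sd, N, S = per_codon_counts(s1, s2, R, frame_offset)
    N_tot, S_tot = float(N.sum()), float(S.sum())
    if N_tot == 0 or S_tot == 0:
        raise ValueError("no comparable codon sites")
    pN = float(nd.sum()) / N_tot
    pS = float(sd.sum()) / S_tot
    return DnDsResult(
        dN=_jc_correct(pN),
        dS=_jc_correct(pS),
        N_sites=N_tot,
        S_sites=S_tot,
        nd=float(nd.sum()),
        sd=float(sd.sum()),
        pN=pN,
        pS=pS,
    )
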