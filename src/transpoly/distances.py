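"""Pairwise nucleotide distances: p, Jukes-Cantor and Kimura 2-parameter.

The K2 model corrects transition (P) and transversion (Q) proportions
separately; it is the substitution model used throughout the tree-building
stages.  Sites where either sequence carries an ambiguous base are excluded
pair-by-pair (pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon import SaturationError, is_transition

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and anything else (N etc.) as -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


_IS_PURINE = np.array([True, False, True, False])  # A C G T


@dataclass(frozen=True)
class PairwiseDistance:
    p: float  # proportion of sites differing
    P: float  # transition proportion
    Q: float  # transversion proportion
    d_jc: float | None
    d_k2: float | None
    n_sites: int
    saturated: bool = False


def _proportions(e1: np.ndarray, e2: np.ndarray) -> tuple[float, float, float, int]:
    ok = (e1 >= 0) & (e2 >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    a, b = e1[ok], e2[ok]
    diff = a != b
    ts = diff & (_IS_PURINE[a] == _IS_PURINE[b])
    P = float(ts.sum()) / n
    Q = float(diff.sum()) / n - P
    return P + Q, P, Q, n


def pairwise_distance(s1: str, s2: str, model: str = "k2") -> PairwiseDistance:
    """Pairwise distance under ``model`` in {'p', 'jc', 'k2'}.

    All three observed proportions are always reported; the corrected
    distances are None (with ``saturated=True``) when the requested model's
    log argument is non-positive, and a :class:`SaturationError` names the
    failing term if the caller asked for that model.
    """
    if model not in ("p", "jc", "k2"):
        raise ValueError(f"unknown model {model!r}")
    e1, e2 = encode(s1), encode(s2)
    if e1.shape != e2.shape:
        raise ValueError("sequences differ in length")
    p, P, Q, n = _proportions(e1, e2)

    d_jc = d_k2 = None
    jc_arg = 1.0 - 4.0 * p / 3.0
    if jc_arg > 0:
        d_jc = -0.75 * np.log(jc_arg)
    k2_a, k2_b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if k2_a > 0 and k2_b > 0:
        d_k2 = -0.5 * np.log(k2_a) - 0.25 * np.log(k2_b)

    saturated = (model == "jc" and d_jc is None) or (model == "k2" and d_k2 is None)
    if saturated:
        raise SaturationError(
            f"{model.upper()} distance undefined: p={p:.4f}, P={P:.4f}, Q={Q:.4f} "
            f"over {n} sites"
        )
    return PairwiseDistance(p=p, P=P, Q=Q, d_jc=d_jc, d_k2=d_k2, n_sites=n)


def k2_ts_tv_ratio(s1: str, s2: str) -> float | None:
    """K2-implied transition/transversion ratio for one pair.

    Ratio of the corrected transitional to transversional distance
    components; None when undefined (no transversions observed, or
    saturation).
    """
    try:
        d = pairwise_distance(s1, s2, model="k2")
    except SaturationError:
        return None
    if d.Q == 0 or d.d_k2 is None:
        return None
    d_tv = -0.5 * np.log(1.0 - 2.0 * d.Q)
    d_ts = d.d_k2 - d_tv
    if d_tv <= 0:
        return None
    return float(d_ts / d_tv)


def distance_matrix(
    seqs: list[str], model: str = "k2", on_saturation: str = "raise"
) -> np.ndarray:
    """Symmetric distance matrix over sequences.

    ``on_saturation``: 'raise' propagates SaturationError naming the pair;
    'nan' records NaN for the saturated pair instead.
    """
    n = len(seqs)
    enc = [encode(s) for s in seqs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, P, Q, _ = _proportions(enc[i], enc[j])
            if model == "p":
                d = p
            elif model == "jc":
                arg = 1.0 - 4.0 * p / 3.0
                d = -0.75 * np.log(arg) if arg > 0 else np.nan
            else:
                a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                d = -0.5 * np.log(a) - 0.25 * np.log(b) if (a > 0 and b > 0) else np.nan
            if np.isnan(d) and on_saturation == "raise":
                raise SaturationError(f"saturated distance between sequences {i} and {j}")
            D[i, j] = D[j, i] = d
    return D


def write_distance_csv(D: np.ndarray, labels: list[str], path) -> None:
    """Square distance matrix as CSV with a label header column."""
    with open(path, "w") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for i, lab in enumerate(labels):
            fh.write(lab + "," + ",".join(f"{v:.6f}" for v in D[i]) + "\n")


def write_phylip_distances(D: np.ndarray, labels: list[str], path) -> None:
    """PHYLIP square distance format (relaxed names)."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, lab in enumerate(labels):
            fh.write(f"{lab:<12s}" + " ".join(f"{v:.6f}" for v in D[i]) + "\n")


def estimate_R(seqs: list[str]) -> float:
    """Data-driven transition/transversion ratio: mean K2-implied ratio
    across all defined pairs (falls back to 1.0 if none are defined)."""
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            r = k2_ts_tv_ratio(seqs[i], seqs[j])
            if r is not None and np.isfinite(r) and r > 0:
                vals.append(r)
    return float(np.mean(vals)) if vals else 1.0


__all__ = [
    "PairwiseDistance",
    "pairwise_distance",
    "distance_matrix",
    "write_distance_csv",
    "write_phylip_distances",
    "k2_ts_tv_ratio",
    "estimate_R",
    "encode",
    "SaturationError",
    "is_transition",
]
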