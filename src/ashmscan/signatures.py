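"""96-context mutation spectra, NMF signature extraction, catalogue comparison.

Substitutions are counted in the standard pyrimidine-centric 96-class
scheme: six substitution types (C>A, C>G, C>T, T>A, T>C, T>G) times the 16
combinations of 5' and 3' flanking bases; purine-reference changes are
reverse-complemented into their pyrimidine class.  Signatures are extracted
by non-negative matrix factorization with multiplicative updates minimizing
the generalized Kullback-Leibler divergence — the de-facto standard for
mutational-signature analysis — and compared to a reference catalogue by
cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import complement, fetch
from .io_core import VariantRecord

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = "ACGT"

#: Canonical ordering of the 96 trinucleotide substitution classes:
#: substitution-major, flanking bases alphabetical.
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in FLANKS for three in FLANKS
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def context_class(ref: str, alt: str, five: str, three: str) -> str | None:
    """Pyrimidine-centric 96-class label for a substitution, or None if Ns."""
    if ref in "GA":  # purine reference: reverse complement the whole context
        ref, alt = complement(ref), complement(alt)
        five, three = complement(three), complement(five)
    label = f"{five}[{ref}>{alt}]{three}"
    return label if label in _CONTEXT_INDEX else None


@dataclass
class MutationSpectrum:
    counts: np.ndarray  # length 96, non-negative ints
    label: str
    n_skipped: int = 0  # unresolvable contexts (N bases / contig edges)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_96), name=self.label)


def build_spectrum(records: Iterable[VariantRecord], genome, label: str) -> MutationSpectrum:
    """Count SNVs into the 96 trinucleotide substitution classes."""
    counts = np.zeros(96, dtype=np.int64)
    n_skipped = 0
    for r in records:
        pos0 = r.pos - 1
        tri = fetch(genome, r.chrom, pos0 - 1, pos0 + 2)
        if pos0 - 1 < 0 or len(tri) < 3:
            n_skipped += 1
            continue
        cls = context_class(r.ref, r.alt, tri[0], tri[2])
        if cls is None:
            n_skipped += 1
            continue
        counts[_CONTEXT_INDEX[cls]] += 1
    if n_skipped:
        logger.warning("spectrum %s: skipped %d variant(s) without resolvable context", label, n_skipped)
    return MutationSpectrum(counts, label, n_skipped)


@dataclass
class SignatureSet:
    """Row-stochastic signatures with compensating non-negative exposures."""

    signatures: np.ndarray  # k x 96, rows sum to 1
    exposures: np.ndarray  # m x k
    objective: list[float]  # KL divergence per iteration of the winning start

    @property
    def k(self) -> int:
        return self.signatures.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.exposures @ self.signatures


_EPS = 1e-12


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def nmf_extract(
    spectra: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> SignatureSet:
    """KL-divergence NMF of an m x 96 spectra matrix by multiplicative updates.

    The best of ``n_starts`` seeded random restarts (by final objective) is
    kept.  The KL objective is verified non-increasing at every iteration;
    signatures are renormalized to row-stochastic form with exposures
    rescaled compensatingly, so exposures are in mutation-count units.
    """
    V = np.asarray(spectra, dtype=float)
    if V.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix")
    if np.any(V < 0):
        raise ValueError("spectra must be non-negative")
    if V.sum() == 0:
        raise ValueError("all-zero spectra matrix")
    m, n = V.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_starts):
        Wm = rng.uniform(0.1, 1.0, size=(m, k)) * scale
        H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
        WH = Wm @ H
        history = [_kl_divergence(V, WH)]
        for _ in range(max_iter):
            # multiplicative updates for generalized KL divergence
            ratio = V / np.maximum(WH, _EPS)
            H *= (Wm.T @ ratio) / np.maximum(Wm.sum(axis=0)[:, None], _EPS)
            WH = Wm @ H
            ratio = V / np.maximum(WH, _EPS)
            Wm *= (ratio @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            WH = Wm @ H
            obj = _kl_divergence(V, WH)
            if obj > history[-1] + 1e-6 * max(1.0, abs(history[-1])):
                raise RuntimeError("KL objective increased — update step is broken")
            converged = history[-1] - obj <= tol * max(1.0, abs(history[-1]))
            history.append(obj)
            if converged:
                break
        if best is None or history[-1] < best[0]:
            best = (history[-1], Wm.copy(), H.copy(), history)

    _, Wm, H, history = best
    row_sums = np.maximum(H.sum(axis=1), _EPS)
    H = H / row_sums[:, None]
    Wm = Wm * row_sums[None, :]
    return SignatureSet(signatures=H, exposures=Wm, objective=history)


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between rows of A and rows of B.

    Zero rows yield NaN (similarity undefined for an empty profile).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = (A @ B.T) / np.outer(na, nb)
    sim[na == 0, :] = np.nan
    sim[:, nb == 0] = np.nan
    return sim


def cosine_to_reference(
    sigset: SignatureSet,
    reference: pd.DataFrame,
    background_threshold: float = 0.75,
) -> pd.DataFrame:
    """Cosine similarity of extracted signatures to a reference catalogue.

    ``reference`` is a 96-row frame indexed by context strings, one column
    per catalogue signature.  Returns a long-format table with an
    ``above_background`` flag at ``background_threshold``; the full matrix
    is always returned, the flag is advisory.
    """
    missing = [c for c in CONTEXTS_96 if c not in reference.index]
    if missing:
        raise ValueError(f"reference catalogue missing contexts, e.g. {missing[:3]}")
    ref = reference.loc[list(CONTEXTS_96)].to_numpy(dtype=float).T  # sigs x 96
    sim = cosine_similarity_matrix(sigset.signatures, ref)
    rows = []
    for i in range(sim.shape[0]):
        for j, name in enumerate(reference.columns):
            rows.append(
                {
                    "signature": f"S{i + 1}",
                    "reference": name,
                    "cosine": sim[i, j],
                    "above_background": bool(sim[i, j] > background_threshold)
                    if not np.isnan(sim[i, j])
                    else False,
                }
            )
    return pd.DataFrame(rows)


def read_reference_catalog(path) -> pd.DataFrame:
    """Read a catalogue TSV: first column context strings, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def spectra_matrix(spectra: Sequence[MutationSpectrum]) -> np.ndarray:
    return np.vstack([s.counts for s in spectra]).astype(float)
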