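"""Phase-locking value (PLV) connectivity and its seed/RSN reductions.

For two phase signals phi_k and phi_l the per-epoch PLV is the modulus of
the mean unit phasor of their phase difference over the epoch's T samples,

    PLV_kl = | (1/T) sum_t exp(-i (phi_k(t) - phi_l(t))) |,

and the subject-level value is the arithmetic mean of per-epoch PLVs across
epochs (PLV is estimated per segment, then averaged across trials). Values
lie in [0, 1]: 1 means a perfectly constant phase lag, ~0 no consistent
phase relation.

Matrices store the diagonal as 1, and every averaging operation excludes it
(intra-seed pairs are never considered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import PhaseSet
from .source_space import RSNSpec, SeedROI

__all__ = [
    "PLVMatrix",
    "SeedFCVector",
    "RSNFCValue",
    "plv_pair",
    "plv_matrix",
    "plv_rows",
    "seed_fc",
    "seed_fc_from_phases",
    "rsn_fc",
]


@dataclass
class PLVMatrix:
    """Per-subject, per-band symmetric source-by-source PLV matrix."""

    subject_id: str
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        self.values = v

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]


@dataclass
class SeedFCVector:
    """Mean FC from a seed to each distant (non-seed) source."""

    subject_id: str
    band: str
    seed_name: str
    values: np.ndarray
    source_indices: np.ndarray  # grid index of each entry of ``values``


@dataclass
class RSNFCValue:
    """Scalar mean intra-network FC for one subject, band and network."""

    subject_id: str
    band: str
    network: str
    value: float
    n_pairs: int


def plv_pair(phase_k: np.ndarray, phase_l: np.ndarray) -> float:
    """Eq.-style pairwise PLV: per-epoch modulus, then mean across epochs.

    Inputs are ``(epochs, samples)`` phase arrays (a single epoch may be
    passed as a 1-D array).
    """
    phase_k = np.atleast_2d(np.asarray(phase_k, dtype=np.float64))
    phase_l = np.atleast_2d(np.asarray(phase_l, dtype=np.float64))
    if phase_k.shape != phase_l.shape:
        raise ValueError("phase arrays must have identical shapes")
    if phase_k.shape[1] < 2:
        raise ValueError("need at least T = 2 samples per epoch")
    per_epoch = np.abs(np.exp(-1j * (phase_k - phase_l)).mean(axis=1))
    return float(per_epoch.mean())


def plv_matrix(phases: PhaseSet, block_size: int = 256) -> PLVMatrix:
    """All-pairs PLV matrix for one subject and band.

    Accumulates, per epoch, the Gram matrix of unit phasors in blocks of
    ``block_size`` source rows, so memory stays bounded for large grids.
    The result is exactly symmetric with a unit diagonal.
    """
    n, n_ep, T = phases.data.shape
    if n < 2:
        raise ValueError("need at least two sources")
    acc = np.zeros((n, n))
    for e in range(n_ep):
        z = np.exp(1j * phases.data[:, e, :])
        for b0 in range(0, n, block_size):
            b1 = min(b0 + block_size, n)
            acc[b0:b1] += np.abs(z[b0:b1] @ z.conj().T) / T
    acc /= n_ep
    acc = (acc + acc.T) / 2.0  # enforce bit-exact symmetry
    np.fill_diagonal(acc, 1.0)
    np.clip(acc, 0.0, 1.0, out=acc)
    return PLVMatrix(
        subject_id=phases.subject_id,
        band=phases.band.name if phases.band is not None else "broadband",
        values=acc,
    )


def plv_rows(phases: PhaseSet, indices) -> np.ndarray:
    """PLV of selected sources against all sources, ``(len(indices), n)``.

    Streaming fast path for seed analyses on large grids, where the full
    matrix is never needed.
    """
    indices = np.asarray(indices, dtype=np.intp)
    n, n_ep, T = phases.data.shape
    acc = np.zeros((len(indices), n))
    for e in range(n_ep):
        z = np.exp(1j * phases.data[:, e, :])
        acc += np.abs(z[indices] @ z.conj().T) / T
    acc /= n_ep
    acc[np.arange(len(indices)), indices] = 1.0
    return np.clip(acc, 0.0, 1.0)


def _seed_reduce(rows: np.ndarray, seed: SeedROI, n: int) -> tuple[np.ndarray, np.ndarray]:
    distant = np.setdiff1d(np.arange(n), seed.source_indices)
    if distant.size == 0:
        raise ValueError("no distant sources: seed covers the whole grid")
    return rows[:, distant].mean(axis=0), distant


def seed_fc(plv: PLVMatrix, seed: SeedROI) -> SeedFCVector:
    """Average seed-to-source PLV into one vector over distant sources.

    For each non-seed source ``s`` the entry is the mean of ``plv[m, s]``
    over seed members ``m``; intra-seed pairs are excluded by construction.
    """
    if np.any(seed.source_indices >= plv.n_sources):
        raise ValueError("seed indices exceed matrix size")
    values, distant = _seed_reduce(plv.values[seed.source_indices], seed, plv.n_sources)
    return SeedFCVector(
        subject_id=plv.subject_id,
        band=plv.band,
        seed_name=seed.name,
        values=values,
        source_indices=distant,
    )


def seed_fc_from_phases(phases: PhaseSet, seed: SeedROI) -> SeedFCVector:
    """Seed FC vector straight from phases, computing only the seed rows."""
    rows = plv_rows(phases, seed.source_indices)
    values, distant = _seed_reduce(rows, seed, phases.n_sources)
    return SeedFCVector(
        subject_id=phases.subject_id,
        band=phases.band.name if phases.band is not None else "broadband",
        seed_name=seed.name,
        values=values,
        source_indices=distant,
    )


def plv_rows_from_analytic(analytic: np.ndarray, indices) -> np.ndarray:
    """PLV rows from a complex analytic signal ``(sources, epochs, samples)``.

    Normalising the analytic signal to unit phasors and forming the Gram
    product is algebraically identical to exponentiating the phase angles,
    but skips the angle/exp round trip.
    """
    indices = np.asarray(indices, dtype=np.intp)
    n, n_ep, T = analytic.shape
    mag = np.abs(analytic)
    if np.any(mag == 0):
        raise ValueError("undefined phase: analytic signal has zero samples")
    acc = np.zeros((len(indices), n))
    for e in range(n_ep):
        z = analytic[:, e, :] / mag[:, e, :]
        acc += np.abs(z[indices] @ z.conj().T) / T
    acc /= n_ep
    acc[np.arange(len(indices)), indices] = 1.0
    return np.clip(acc, 0.0, 1.0)


def seed_fc_from_analytic(
    analytic: np.ndarray, seed: SeedROI, subject_id: str, band: str
) -> SeedFCVector:
    """Seed FC vector from the fused analytic-signal path."""
    rows = plv_rows_from_analytic(analytic, seed.source_indices)
    values, distant = _seed_reduce(rows, seed, analytic.shape[0])
    return SeedFCVector(
        subject_id=subject_id, band=band, seed_name=seed.name,
        values=values, source_indices=distant,
    )


def rsn_fc(plv: PLVMatrix, rsn: RSNSpec, pair_policy: str = "all_pairs") -> RSNFCValue:
    """Mean PLV over an RSN's source pairs.

    ``pair_policy``:

    - ``"all_pairs"`` (default): all unordered pairs of distinct RSN
      sources, the literal reading of averaging "all the sources included"
      in the network's spheres;
    - ``"between_spheres"``: only pairs whose members belong to different
      centers' spheres, for readers of the same sentence who take the
      within-sphere pairs to be excluded.

    The diagonal is never included.
    """
    idx = rsn.source_indices
    if idx.size == 0:
        raise ValueError("RSN has no sources")
    if pair_policy == "all_pairs":
        if idx.size < 2:
            raise ValueError("all_pairs policy needs at least two RSN sources")
        sub = plv.values[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        vals = sub[iu]
    elif pair_policy == "between_spheres":
        # sphere label per source; sources in several spheres belong to each
        pairs = set()
        for a in range(len(rsn.center_membership)):
            for b in range(a + 1, len(rsn.center_membership)):
                for i in rsn.center_membership[a]:
                    for j in rsn.center_membership[b]:
                        if i != j:
                            pairs.add((min(i, j), max(i, j)))
        if not pairs:
            raise ValueError("between_spheres policy selected no pairs")
        arr = np.asarray(sorted(pairs), dtype=np.intp)
        vals = plv.values[arr[:, 0], arr[:, 1]]
    else:
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    return RSNFCValue(
        subject_id=plv.subject_id,
        band=plv.band,
        network=rsn.name,
        value=float(vals.mean()),
        n_pairs=int(vals.size),
    )
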