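"""Synthetic two-group source-space cohorts with controllable phase coupling.

Every source is a narrowband oscillator: its phase is a linear ramp at a
carrier frequency drawn inside the source's band, plus a slow Gaussian
random-walk that gives the line a realistic width. The observed signal is
the cosine of the phase plus white observation noise.

Coupling is a driven-source model: the driven member of a pair copies the
driver's phase up to a fixed lag plus a stochastic phase offset whose
circular mean resultant equals the target PLV. Two offset models are
available:

- ``"pm"`` (default): slow sinusoidal phase modulation with depth
  ``A = J0^{-1}(rho)`` and an integer number of modulation cycles per
  epoch, so the expected per-epoch PLV is exactly ``J0(A) = rho``. Because
  the modulation is slow, the coupling survives band-pass filtering and the
  full pipeline (filter -> Hilbert phase -> PLV) recovers ``rho``.
- ``"vonmises_iid"``: i.i.d. von Mises offsets per sample with
  concentration ``kappa_for_plv(rho)``, so the sample-level expected PLV is
  the Bessel ratio ``I1(kappa)/I0(kappa) = rho``. This is the natural model
  at the phase level, but the jitter is spectrally broadband: a band-pass
  filter strips most of it, so pipeline-recovered PLV is biased far above
  ``rho``. It is kept for phase-level studies and as a cautionary contrast.

A frail-specific effect reduces the coupling of designated seed-target
pairs from ``rho_robust`` to ``rho_robust - delta_rho`` in the frail group,
in the effect band only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e, j0

from .clinical import ClinicalTable
from .preprocessing import DEFAULT_BANDS, BandSpec
from .source_space import SeedROI, SourceGrid, build_regular_grid

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "CouplingSpec",
    "GeneratedCohort",
    "SubjectRecord",
    "kappa_for_plv",
    "expected_plv_vonmises",
    "pm_depth_for_plv",
    "simulate_subject",
    "simulate_cohort",
    "simulate_clinical",
    "ClinicalVariableSpec",
    "default_clinical_variables",
    "default_grid",
]

_J0_FIRST_ZERO = 2.404825557695773


def expected_plv_vonmises(kappa: float) -> float:
    """Expected PLV of i.i.d. von Mises phase offsets: I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_plv(rho: float) -> float:
    """Von Mises concentration whose Bessel ratio I1/I0 equals ``rho``.

    Solved numerically to |I1(k)/I0(k) - rho| < 1e-10. ``rho`` must be in
    [0, 1); perfect locking is unattainable at finite concentration.
    """
    if not 0 <= rho < 1:
        raise ValueError("target PLV must be in [0, 1)")
    if rho == 0:
        return 0.0
    lo, hi = 1e-12, 2.0
    while expected_plv_vonmises(hi) < rho:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - rho this close to 1 is rejected above
            raise ValueError("target PLV too close to 1")
    return float(brentq(lambda k: expected_plv_vonmises(k) - rho, lo, hi, xtol=1e-12))


def pm_depth_for_plv(rho: float) -> float:
    """Sinusoidal phase-modulation depth A with J0(A) = rho."""
    if not 0 <= rho < 1:
        raise ValueError("target PLV must be in [0, 1)")
    if rho == 0:
        return _J0_FIRST_ZERO
    return float(brentq(lambda a: j0(a) - rho, 0.0, _J0_FIRST_ZERO))


@dataclass(frozen=True)
class CouplingSpec:
    """One driven pair: source ``driver`` entrains source ``driven`` at
    target PLV ``rho`` within ``band``."""

    driver: int
    driven: int
    rho: float
    band: str = "upper_beta"

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.driver == self.driven:
            raise ValueError("a source cannot drive itself")


@dataclass(frozen=True)
class EffectSpec:
    """Frail-specific hypo-connectivity between a seed and a target cluster.

    Each target source is driven by one seed source at ``rho_robust`` in
    the robust group and ``rho_robust - delta_rho`` in the frail group,
    in ``band`` only. The target region must be contiguous under the
    analysis adjacency (checked by the caller that owns the adjacency).
    """

    seed: SeedROI
    target_indices: np.ndarray
    band: str = "upper_beta"
    rho_robust: float = 0.45
    delta_rho: float = 0.15

    def __post_init__(self) -> None:
        t = np.asarray(self.target_indices, dtype=np.intp)
        if t.size == 0:
            raise ValueError("effect target region is empty")
        if self.rho_robust - self.delta_rho < 0:
            raise ValueError("rho_robust - delta_rho must be non-negative")
        if not 0 <= self.rho_robust < 1:
            raise ValueError("rho_robust must be in [0, 1)")
        object.__setattr__(self, "target_indices", t)

    def pairs_for_group(self, group: str) -> list[CouplingSpec]:
        rho = self.rho_robust if group == "robust" else self.rho_robust - self.delta_rho
        seed_idx = self.seed.source_indices
        return [
            CouplingSpec(
                driver=int(seed_idx[k % len(seed_idx)]),
                driven=int(t),
                rho=rho,
                band=self.band,
            )
            for k, t in enumerate(self.target_indices)
        ]


def default_grid(shape=(5, 5, 4), spacing: float = 10.0) -> SourceGrid:
    """Desk-scale regular grid (default 100 sources at 10 mm spacing)."""
    box = tuple((0.0, spacing * (s - 1)) for s in shape)
    return build_regular_grid(box, spacing)


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic two-group cohort.

    Group sizes and per-subject epoch counts default to the frail/robust
    study conditions: 34 robust and 20 frail subjects, with epoch counts
    drawn as round(Normal(mu, sd)) clipped at 20 from (81.0, 13.1) for the
    robust and (77.5, 12.1) for the frail group, at 1000 Hz with 4-s
    epochs.
    """

    n_robust: int = 34
    n_frail: int = 20
    grid: SourceGrid = field(default_factory=default_grid)
    fs: float = 1000.0
    epoch_len: float = 4.0
    epochs_mean_robust: float = 81.0
    epochs_sd_robust: float = 13.1
    epochs_mean_frail: float = 77.5
    epochs_sd_frail: float = 12.1
    min_epochs: int = 20
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    source_band: str = "upper_beta"  # carrier band when multiband_background=False
    multiband_background: bool = True  # every source carries one oscillator per band
    base_coupling: tuple[CouplingSpec, ...] = ()
    effect: EffectSpec | None = None
    sigma_obs: float = 0.2
    phase_walk_sd: float = 0.05  # rad per sample
    modulation_freq: float | None = None  # default: 1 cycle per second
    coupling_model: str = "pm"  # or "vonmises_iid"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_robust < 2 or self.n_frail < 2:
            raise ValueError("both groups need at least two subjects")
        if self.coupling_model not in ("pm", "vonmises_iid"):
            raise ValueError("coupling_model must be 'pm' or 'vonmises_iid'")
        names = {b.name for b in self.bands}
        if self.source_band not in names:
            raise ValueError(f"source_band {self.source_band!r} not among bands")
        for c in self.base_coupling:
            if c.band not in names:
                raise ValueError(f"coupling band {c.band!r} not among bands")
        self._check_driven_unique()

    def _check_driven_unique(self) -> None:
        pairs = list(self.base_coupling)
        if self.effect is not None:
            pairs += self.effect.pairs_for_group("robust")
        driven = [c.driven for c in pairs]
        if len(driven) != len(set(driven)):
            raise ValueError(
                "conflicting coupling graph: each source may be the driven "
                "member of at most one pair"
            )
        drivers = {c.driver for c in pairs}
        if drivers & set(driven):
            raise ValueError("a driven source cannot also drive another pair")

    def band_by_name(self, name: str) -> BandSpec:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def pairs_for_group(self, group: str) -> list[CouplingSpec]:
        pairs = list(self.base_coupling)
        if self.effect is not None:
            pairs += self.effect.pairs_for_group(group)
        return pairs


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    n_epochs: int
    data: np.ndarray | None = None  # (sources, samples); None when on disk
    path: str | None = None


@dataclass
class GeneratedCohort:
    """Simulated cohort plus the ground truth needed to predict every PLV."""

    spec: CohortSpec
    subjects: list[SubjectRecord]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "n_epochs": [s.n_epochs for s in self.subjects],
                "path": [s.path or "" for s in self.subjects],
            }
        )

    def truth(self) -> dict:
        """Coupling graph with model-predicted PLV for every coupled pair."""
        link = (
            (lambda rho: rho)  # J0(A(rho)) == rho and I1/I0(kappa(rho)) == rho
        )
        out = {"rng_seed": self.spec.rng_seed, "coupling_model": self.spec.coupling_model}
        per_group = {}
        for group in ("robust", "frail"):
            per_group[group] = [
                {
                    "driver": c.driver,
                    "driven": c.driven,
                    "band": c.band,
                    "target_plv": c.rho,
                    "expected_plv": link(c.rho),
                }
                for c in self.spec.pairs_for_group(group)
            ]
        out["pairs"] = per_group
        if self.spec.effect is not None:
            out["effect"] = {
                "seed": self.spec.effect.seed.name,
                "seed_indices": self.spec.effect.seed.source_indices.tolist(),
                "target_indices": self.spec.effect.target_indices.tolist(),
                "band": self.spec.effect.band,
                "rho_robust": self.spec.effect.rho_robust,
                "delta_rho": self.spec.effect.delta_rho,
            }
        return out


def _modulation_freq(spec: CohortSpec) -> float:
    if spec.modulation_freq is not None:
        fm = spec.modulation_freq
    else:
        fm = 1.0
    # an integer number of modulation cycles per epoch keeps E[PLV] = J0(A)
    cycles = fm * spec.epoch_len
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError("modulation_freq must give an integer cycle count per epoch")
    return fm


def _carrier(rng: np.random.Generator, band: BandSpec, margin: float) -> float:
    lo, hi = band.lo + margin, band.hi - margin
    if lo >= hi:  # band too narrow for the requested margin; use the center
        return 0.5 * (band.lo + band.hi)
    return float(rng.uniform(lo, hi))


def simulate_subject(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    n_epochs: int | None = None,
) -> np.ndarray:
    """Continuous source time series for one subject, ``(sources, samples)``.

    Per band component, each source's phase is
    ``phi_s(t) = 2 pi f_s t + theta_s + w_s(t)`` with the carrier ``f_s``
    uniform inside the band, ``theta_s`` uniform and ``w_s`` a Gaussian
    random walk. Driven sources copy their driver's phase in the coupling's
    band plus a fixed lag and the coupling offset process. The signal sums
    the band components' cosines plus white observation noise.

    With ``multiband_background`` disabled every source carries only a
    ``source_band`` oscillator; the default multi-band background exists so
    that each analysis band sees genuine in-band activity rather than the
    spectral tail of a distant line, as resting-state recordings do.
    """
    if group not in ("robust", "frail"):
        raise ValueError("group must be 'robust' or 'frail'")
    if n_epochs is None:
        n_epochs = draw_epoch_count(spec, group, rng)
    n_src = spec.grid.n_sources
    T = round(spec.epoch_len * spec.fs)
    N = n_epochs * T
    # single precision throughout: phase errors from float32 argument
    # reduction (~1e-3 rad over a full recording) are far below the
    # generator's own phase-walk noise
    t = (np.arange(N) / spec.fs).astype(np.float32)

    pairs = spec.pairs_for_group(group)
    fm = _modulation_freq(spec)

    # under PM coupling the driver's carrier keeps a margin so the driven
    # copy's modulation sidebands stay inside the band
    driver_margin: dict[int, float] = {}
    if spec.coupling_model == "pm":
        for c in pairs:
            A = pm_depth_for_plv(c.rho)
            m = (A + 1.0) * fm + 1.0
            driver_margin[c.driver] = max(driver_margin.get(c.driver, 0.0), m)

    bands = (
        spec.bands if spec.multiband_background
        else (spec.band_by_name(spec.source_band),)
    )
    x = np.zeros((n_src, N), dtype=np.float32)
    for band in bands:
        carriers = rng.uniform(band.lo + 1.0, band.hi - 1.0, n_src)
        for drv, margin in driver_margin.items():
            carriers[drv] = _carrier(rng, band, margin)
        thetas = rng.uniform(0.0, 2.0 * np.pi, n_src)
        walks = rng.standard_normal((n_src, N), dtype=np.float32)
        walks *= spec.phase_walk_sd
        np.cumsum(walks, axis=1, out=walks)
        phases = (2.0 * np.pi) * carriers[:, None].astype(np.float32) * t
        phases += thetas[:, None].astype(np.float32)
        phases += walks
        del walks
        for c in pairs:
            if c.band != band.name:
                continue
            delta = rng.uniform(0.0, 2.0 * np.pi)
            if spec.coupling_model == "pm":
                A = pm_depth_for_plv(c.rho)
                psi = rng.uniform(0.0, 2.0 * np.pi)
                eps = (A * np.cos(2.0 * np.pi * fm * t + psi)).astype(np.float32)
            else:
                kappa = kappa_for_plv(c.rho)
                eps = (
                    rng.vonmises(0.0, kappa, N)
                    if kappa > 0
                    else rng.uniform(-np.pi, np.pi, N)
                ).astype(np.float32)
            phases[c.driven] = phases[c.driver] + np.float32(delta) + eps
        x += np.cos(phases)
    noise = rng.standard_normal(x.shape, dtype=np.float32)
    x += np.float32(spec.sigma_obs) * noise
    return x


def draw_epoch_count(spec: CohortSpec, group: str, rng: np.random.Generator) -> int:
    mu, sd = (
        (spec.epochs_mean_robust, spec.epochs_sd_robust)
        if group == "robust"
        else (spec.epochs_mean_frail, spec.epochs_sd_frail)
    )
    return int(max(spec.min_epochs, round(rng.normal(mu, sd))))


def simulate_cohort(spec: CohortSpec, write_dir=None) -> GeneratedCohort:
    """Simulate every subject with an independent child RNG stream.

    With ``write_dir`` set, each subject's continuous data goes to an HDF5
    file and a TSV manifest plus ``truth.json`` are written; otherwise data
    stay in memory.
    """
    ss = np.random.SeedSequence(spec.rng_seed)
    n_total = spec.n_robust + spec.n_frail
    children = ss.spawn(n_total)
    groups = ["robust"] * spec.n_robust + ["frail"] * spec.n_frail
    subjects: list[SubjectRecord] = []
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        n_ep = draw_epoch_count(spec, group, rng)
        data = simulate_subject(spec, group, rng, n_epochs=n_ep)
        sid = f"sub-{i + 1:03d}"
        rec = SubjectRecord(subject_id=sid, group=group, n_epochs=n_ep, data=data)
        if write_dir is not None:
            from . import io as plio

            write_dir = Path(write_dir)
            write_dir.mkdir(parents=True, exist_ok=True)
            path = write_dir / f"{sid}.h5"
            plio.save_continuous(path, data, spec.fs, sid)
            rec = replace_data_with_path(rec, str(path))
        subjects.append(rec)
    cohort = GeneratedCohort(spec=spec, subjects=subjects)
    if write_dir is not None:
        cohort.manifest.to_csv(Path(write_dir) / "manifest.tsv", sep="\t", index=False)
        with open(Path(write_dir) / "truth.json", "w") as fh:
            json.dump(cohort.truth(), fh, indent=1)
        from . import io as plio

        plio.save_grid(Path(write_dir) / "grid.h5", spec.grid)
    return cohort


def replace_data_with_path(rec: SubjectRecord, path: str) -> SubjectRecord:
    return SubjectRecord(
        subject_id=rec.subject_id,
        group=rec.group,
        n_epochs=rec.n_epochs,
        data=None,
        path=path,
    )


@dataclass(frozen=True)
class ClinicalVariableSpec:
    """One synthetic clinical variable.

    ``kind`` is ``"categorical"`` (params: per-group probability of the
    reference level, e.g. ``{"robust": 21/34, "frail": 15/20}``, levels
    default ``("F", "M")``) or ``"continuous"`` (params: per-group
    ``(mean, sd)`` of a normal distribution).
    """

    name: str
    kind: str
    params: dict
    levels: tuple[str, str] = ("F", "M")

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError("kind must be 'categorical' or 'continuous'")
        if self.kind == "categorical":
            for g, p in self.params.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability for group {g!r} outside [0, 1]")


def default_clinical_variables() -> list[ClinicalVariableSpec]:
    """Variables shaped like a frailty demographics table: gender with the
    21/34 vs 15/20 female proportions, plus age-like and score-like
    continuous variables with a modest group shift."""
    return [
        ClinicalVariableSpec(
            "gender", "categorical", {"robust": 21 / 34, "frail": 15 / 20}
        ),
        ClinicalVariableSpec(
            "age", "continuous", {"robust": (78.0, 5.0), "frail": (80.5, 4.5)}
        ),
        ClinicalVariableSpec(
            "gait_speed", "continuous", {"robust": (1.05, 0.2), "frail": (0.7, 0.2)}
        ),
    ]


def simulate_clinical(
    n_robust: int,
    n_frail: int,
    variables: list[ClinicalVariableSpec] | None = None,
    rng_seed: int = 0,
) -> ClinicalTable:
    """Typed clinical table ready for :func:`phaselock.clinical.summarize`."""
    variables = variables if variables is not None else default_clinical_variables()
    if not variables:
        raise ValueError("need at least one variable spec")
    rng = np.random.default_rng(rng_seed)
    groups = ["robust"] * n_robust + ["frail"] * n_frail
    data = {
        "subject_id": [f"sub-{i + 1:03d}" for i in range(len(groups))],
        "group": groups,
    }
    types = {}
    for var in variables:
        col = []
        for g in groups:
            if var.kind == "categorical":
                p = var.params[g]
                col.append(var.levels[0] if rng.uniform() < p else var.levels[1])
            else:
                mu, sd = var.params[g]
                col.append(float(rng.normal(mu, sd)))
        data[var.name] = col
        types[var.name] = var.kind
    return ClinicalTable(data=pd.DataFrame(data), types=types)
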