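"""Synthetic cohorts with known ground truth.

Emulates the home-fNIRS study design: ~11 chronic stroke survivors each
performing 10 trials of a 10 s fist-squeeze task followed by 40 s rest,
recorded at 5.4 Hz on the 8 x 2 headband grid. A per-participant latent
upper-extremity impairment/function trait drives (i) ordinal FM-12 and
SIS-Hand item responses through probit links and (ii) hemispheric
asymmetry of the task-evoked hemodynamic response, so parameter recovery
can be scored against stored truth.

Raw recordings are built in concentration space (task response +
physiological oscillations in the cardiac/respiration/Mayer bands with
per-channel delays), pushed through the forward modified Beer-Lambert
model to optical density, and exponentiated to strictly positive
two-wavelength intensities, so the preprocessing chain inverts an honest
forward model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .montage import Montage, build_montage
from .preprocess import EXTINCTION, RawRecording, mbll_forward

__all__ = [
    "SimConfig",
    "SimTruth",
    "ItemResponses",
    "INSTRUMENTS",
    "canonical_hrf",
    "generate_item_responses",
    "generate_recording",
    "generate_sem_cohort",
    "generate_cohort",
    "default_fm_cutpoints",
    "default_sis_cutpoints",
]

# instrument -> (n_items, n_categories, first category label)
INSTRUMENTS: dict[str, tuple[int, int, int]] = {
    "FM12": (12, 3, 0),  # 12 items scored 0-2
    "SISHand": (5, 5, 1),  # 5 items scored 1-5
}


def default_fm_cutpoints() -> list[np.ndarray]:
    """Per-item cutpoints for the 12 FM items (3 categories, 2 cuts),
    with item-to-item difficulty shifts spanning the ability range."""
    shifts = np.linspace(-0.9, 0.9, 12)
    return [np.array([-0.7, 0.7]) + s for s in shifts]


def default_sis_cutpoints() -> list[np.ndarray]:
    """Per-item cutpoints for the 5 SIS-Hand items (5 categories, 4 cuts)."""
    shifts = np.linspace(-0.5, 0.5, 5)
    return [np.array([-1.2, -0.4, 0.4, 1.2]) + s for s in shifts]


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study's task design."""

    n_participants: int = 11
    n_trials: int = 10
    task_s: float = 10.0
    rest_s: float = 40.0
    lead_in_s: float = 30.0  # rest before trial 1 so filters can settle
    fs: float = 5.4

    hrf_peak_s: float = 6.0
    hrf_amplitude: float = 1.0  # µM peak ΔHbO of the evoked response
    hbr_ratio: float = 1.0 / 3.0  # evoked ΔHb = -hbr_ratio * ΔHbO

    band_amplitudes: dict = field(
        default_factory=lambda: {"cardiac": 0.8, "respiration": 0.4, "mayer": 0.6}
    )  # µM
    band_frequencies: dict = field(
        default_factory=lambda: {"cardiac": 1.1, "respiration": 0.22, "mayer": 0.095}
    )  # Hz, inside the nominal bands
    band_delay_range: dict = field(
        default_factory=lambda: {"cardiac": 0.2, "respiration": 0.5, "mayer": 1.0}
    )  # s, per-channel delays drawn U(-range, range)
    physio_hbr_ratio: float = 0.5  # systemic oscillation leak into ΔHb
    physio_hbr_lag_s: dict = field(
        default_factory=lambda: {"cardiac": 0.2, "respiration": 0.8, "mayer": 2.5}
    )  # ΔHb oscillations lag ΔHbO by about a quarter period per band

    pair_mean: float = 0.02  # µM/s baseline asymmetry common to all pairs
    m1lat_scale: float = 0.04  # µM/s per unit location latent
    pair_loadings: tuple = tuple(
        round(float(x), 4) for x in np.linspace(0.3, 0.9, 8)
    )
    trial_noise_sd: float = 0.04  # µM/s heavy-tailed trial-to-trial noise
    trial_noise_df: float = 8.0
    noise_sd_spread: float = 0.3  # lognormal sd of per-(participant, location)
    # noise scales: home recordings differ in optode coupling and movement

    motion_rate: float = 0.6  # artifacts per minute
    motion_amplitude_od: float = 0.03  # optical-density units
    od_noise_sd: float = 0.002  # Gaussian sensor noise, OD units
    baseline_intensity: float = 1.0e6  # arbitrary detector units
    short_hrf_fraction: float = 0.1  # evoked leak into short channels

    true_rho_fm: float = 0.8
    true_rho_sis: float = 0.85
    true_rho_m1lat: float = 0.44
    latent_df: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.true_rho_fm <= 1.0 and 0.0 <= self.true_rho_sis <= 1.0):
            raise ValueError("true_rho_fm/true_rho_sis must lie in [0, 1]")
        if abs(self.true_rho_m1lat) > 1.0:
            raise ValueError("|true_rho_m1lat| must be <= 1")
        if any(not (0.0 < l < 1.0) for l in self.pair_loadings):
            raise ValueError("pair loadings must lie in (0, 1)")
        if len(self.pair_loadings) != 8:
            raise ValueError("need exactly 8 pair loadings")

    @property
    def trial_period_s(self) -> float:
        return self.task_s + self.rest_s

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.n_trials * self.trial_period_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def onsets(self) -> np.ndarray:
        return self.lead_in_s + np.arange(self.n_trials) * self.trial_period_s


@dataclass
class SimTruth:
    """Ground truth stored with every generated cohort."""

    config: SimConfig
    participant_ids: list[str]
    lesion_sides: list[str]
    latent: np.ndarray  # per-participant UE-IF draw
    fm_trait: np.ndarray
    sis_trait: np.ndarray
    m1_trait: np.ndarray
    location_latents: np.ndarray  # (n, 8)
    m1lat_mean: np.ndarray  # (n, 8), µM/s true per-pair M1-LAT means
    noise_sd: np.ndarray  # (n, 8), µM/s per-(participant, location) trial noise
    fm_cutpoints: list
    sis_cutpoints: list

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "participant_ids": self.participant_ids,
            "lesion_sides": self.lesion_sides,
            "latent": self.latent.tolist(),
            "fm_trait": self.fm_trait.tolist(),
            "sis_trait": self.sis_trait.tolist(),
            "m1_trait": self.m1_trait.tolist(),
            "location_latents": self.location_latents.tolist(),
            "m1lat_mean": self.m1lat_mean.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "fm_cutpoints": [np.asarray(c).tolist() for c in self.fm_cutpoints],
            "sis_cutpoints": [np.asarray(c).tolist() for c in self.sis_cutpoints],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d.pop("config")
        cfg["pair_loadings"] = tuple(cfg["pair_loadings"])
        return cls(
            config=SimConfig(**cfg),
            participant_ids=d["participant_ids"],
            lesion_sides=d["lesion_sides"],
            latent=np.array(d["latent"]),
            fm_trait=np.array(d["fm_trait"]),
            sis_trait=np.array(d["sis_trait"]),
            m1_trait=np.array(d["m1_trait"]),
            location_latents=np.array(d["location_latents"]),
            m1lat_mean=np.array(d["m1lat_mean"]),
            noise_sd=np.array(d["noise_sd"]),
            fm_cutpoints=[np.array(c) for c in d["fm_cutpoints"]],
            sis_cutpoints=[np.array(c) for c in d["sis_cutpoints"]],
        )


class ItemResponses:
    """Ordinal FM-12 / SIS-Hand responses as a validated long table."""

    def __init__(self, table: pd.DataFrame):
        required = {"participant_id", "instrument", "item", "response"}
        if not required.issubset(table.columns):
            raise ValueError(f"item table needs columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        unknown = set(t["instrument"]) - set(INSTRUMENTS)
        if unknown:
            raise ValueError(f"unknown instruments {sorted(unknown)}")
        dup = t.duplicated(["participant_id", "instrument", "item"])
        if dup.any():
            raise ValueError(
                f"duplicated (participant, instrument, item) at rows "
                f"{t.index[dup].tolist()}"
            )
        for inst, (n_items, n_cat, first) in INSTRUMENTS.items():
            sub = t[t["instrument"] == inst]
            bad_item = sub[(sub["item"] < 1) | (sub["item"] > n_items)]
            if len(bad_item):
                raise ValueError(
                    f"{inst}: item index out of range at rows "
                    f"{bad_item.index.tolist()}"
                )
            bad = sub[(sub["response"] < first) | (sub["response"] > first + n_cat - 1)]
            if len(bad):
                raise ValueError(
                    f"{inst}: response out of category range at rows "
                    f"{bad.index.tolist()}"
                )

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.table["participant_id"].unique())

    def to_arrays(self, participant_ids: list[str] | None = None):
        """Return (fm, sis) integer matrices with categories starting at 0."""
        pids = participant_ids or self.participant_ids
        out = {}
        for inst, (n_items, _, first) in INSTRUMENTS.items():
            mat = np.full((len(pids), n_items), -1, dtype=int)
            sub = self.table[self.table["instrument"] == inst]
            for r in sub.itertuples():
                mat[pids.index(r.participant_id), r.item - 1] = r.response - first
            if np.any(mat < 0):
                raise ValueError(f"missing {inst} items for some participants")
            out[inst] = mat
        return out["FM12"], out["SISHand"]


# ---------------------------------------------------------------------------
# hemodynamic response


@lru_cache(maxsize=8)
def _hrf_norm(peak_s: float, undershoot_s: float, ratio: float) -> float:
    t = np.arange(0.0, 40.0, 1e-3)
    return float(np.max(_hrf_raw(t, peak_s, undershoot_s, ratio)))


def _hrf_raw(t, peak_s, undershoot_s, ratio):
    a1, a2 = 6.0, 16.0
    b1 = peak_s / (a1 - 1.0)
    b2 = undershoot_s / (a2 - 1.0)
    return stats.gamma.pdf(t, a1, scale=b1) - ratio * stats.gamma.pdf(
        t, a2, scale=b2
    )


def canonical_hrf(
    t, peak_s: float = 6.0, undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0
):
    """Double-gamma hemodynamic impulse response, peak normalized to 1.

    Zero at onset, peaks at ``peak_s`` seconds, with a late undershoot
    and decay to baseline by ~40 s. Raises on negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("canonical_hrf is defined for t >= 0")
    out = _hrf_raw(t, peak_s, undershoot_s, ratio) / _hrf_norm(
        peak_s, undershoot_s, ratio
    )
    return float(out) if out.ndim == 0 else out


def _unit_response(config: SimConfig) -> np.ndarray:
    """Single-trial response: task boxcar convolved with the HRF, sampled
    at fs and normalized to unit peak. Long enough to decay fully."""
    dt = 1.0 / config.fs
    n_kernel = int(round(40.0 * config.fs))
    kernel = canonical_hrf(np.arange(n_kernel) * dt, config.hrf_peak_s)
    box = np.ones(max(1, int(round(config.task_s * config.fs))))
    resp = np.convolve(box, kernel) * dt
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def _response_slope(config: SimConfig) -> float:
    """OLS slope (1/s) of the unit response over the task window."""
    u = _unit_response(config)
    n_task = int(round(config.task_s * config.fs))
    t = np.arange(n_task) / config.fs
    y = u[:n_task] - u[0]
    t_c = t - t.mean()
    return float((t_c @ y) / (t_c @ t_c))


# ---------------------------------------------------------------------------
# item responses


def generate_item_responses(
    latent_trait: float,
    rho: float,
    cutpoints: list[np.ndarray],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Ordinal responses for one participant on one instrument.

    Each item's propensity is drawn Normal(rho * latent_trait, 1) and the
    response is the count of that item's cutpoints lying below it (first
    category = 0 here; instrument offsets are applied by the cohort
    assembler). Cutpoints must be strictly increasing per item.
    """
    if abs(rho) > 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    responses = np.empty(len(cutpoints), dtype=int)
    for j, cuts in enumerate(cutpoints):
        cuts = np.asarray(cuts, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError(f"item {j + 1}: cutpoints must be strictly increasing")
        propensity = rho * latent_trait + rng.normal()
        responses[j] = int(np.sum(cuts < propensity))
    return responses


# ---------------------------------------------------------------------------
# cohort-level truth


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    n = config.n_participants
    eta = rng.standard_t(config.latent_df, size=n)
    lam = np.asarray(config.pair_loadings)

    def subtrait(rho):
        return rho * eta + np.sqrt(1.0 - rho**2) * rng.normal(size=n)

    fm = subtrait(config.true_rho_fm)
    sis = subtrait(config.true_rho_sis)
    m1 = subtrait(config.true_rho_m1lat)
    g = lam * m1[:, None] + np.sqrt(1.0 - lam**2) * rng.normal(size=(n, 8))
    mu = config.pair_mean + config.m1lat_scale * g
    noise_sd = config.trial_noise_sd * np.exp(
        config.noise_sd_spread * rng.normal(size=(n, 8))
    )
    return SimTruth(
        config=config,
        participant_ids=[f"P{i + 1:02d}" for i in range(n)],
        lesion_sides=[("left", "right")[int(b)] for b in rng.integers(0, 2, n)],
        latent=eta,
        fm_trait=fm,
        sis_trait=sis,
        m1_trait=m1,
        location_latents=g,
        m1lat_mean=mu,
        noise_sd=noise_sd,
        fm_cutpoints=default_fm_cutpoints(),
        sis_cutpoints=default_sis_cutpoints(),
    )


def _draw_items(truth: SimTruth, rng: np.random.Generator) -> ItemResponses:
    rows = []
    for i, pid in enumerate(truth.participant_ids):
        for inst, trait, cuts in (
            ("FM12", truth.fm_trait[i], truth.fm_cutpoints),
            ("SISHand", truth.sis_trait[i], truth.sis_cutpoints),
        ):
            first = INSTRUMENTS[inst][2]
            resp = generate_item_responses(trait, 1.0, cuts, rng)
            rows += [
                {
                    "participant_id": pid,
                    "instrument": inst,
                    "item": j + 1,
                    "response": int(r) + first,
                }
                for j, r in enumerate(resp)
            ]
    return ItemResponses(pd.DataFrame(rows))


def _draw_trial_noise(
    config: SimConfig, rng: np.random.Generator, noise_sd_row: np.ndarray
) -> np.ndarray:
    return noise_sd_row * rng.standard_t(
        config.trial_noise_df, size=(config.n_trials, 8)
    )


# ---------------------------------------------------------------------------
# raw recordings


def generate_recording(
    config: SimConfig,
    truth: SimTruth,
    participant_index: int,
    seed: int | np.random.Generator,
    montage: Montage | None = None,
    trial_noise: np.ndarray | None = None,
) -> RawRecording:
    """Two-wavelength intensity recording for one participant.

    Hemispheric gains are set so the contralesional-minus-ipsilesional
    task-window slope difference at pair *l* on trial *k* equals the true
    per-pair M1-LAT mean plus that trial's heavy-tailed noise draw.
    Physiological oscillations (one per band, with per-channel delays)
    and optional motion spikes/steps ride on top; short channels carry
    full physiology but only a small fraction of the evoked gain.
    """
    if seed is None:
        raise ValueError("a seed is required: recordings must be reproducible")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mont = montage or build_montage()
    i = participant_index
    lesion = truth.lesion_sides[i]
    n = config.n_samples
    t = np.arange(n) / config.fs
    onsets = config.onsets()
    u = _unit_response(config)
    s_r = _response_slope(config)
    if trial_noise is None:
        trial_noise = _draw_trial_noise(config, rng, truth.noise_sd[i])

    # per-(trial, pair, hemisphere) gains; "contra" = hemisphere opposite lesion
    mu = truth.m1lat_mean[i]  # (8,)
    target = mu[None, :] + trial_noise  # (trials, 8)
    half = target / (2.0 * s_r) if s_r != 0 else np.zeros_like(target)
    gain_contra = config.hrf_amplitude + half
    gain_ipsi = config.hrf_amplitude - half

    # physiological common components
    bands = list(config.band_amplitudes)
    freqs = {b: config.band_frequencies[b] for b in bands}
    phases = {b: rng.uniform(0.0, 2.0 * np.pi) for b in bands}
    channel_ids = [c.id for c in mont.channels]
    delays = {
        b: rng.uniform(
            -config.band_delay_range[b],
            config.band_delay_range[b],
            size=len(channel_ids),
        )
        for b in bands
    }

    onset_idx = np.round(onsets * config.fs).astype(int)

    def evoked(gains_per_trial: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        for k, start in enumerate(onset_idx):
            stop = min(n, start + u.size)
            out[start:stop] += gains_per_trial[k] * u[: stop - start]
        return out

    hbo = np.zeros((len(channel_ids), n))
    hbr = np.zeros_like(hbo)
    for c_idx, ch in enumerate(mont.channels):
        if ch.path_type == "long":
            l = ch.pair_index - 1
            gains = gain_ipsi[:, l] if ch.hemisphere == lesion else gain_contra[:, l]
            resp = evoked(gains)
        else:
            resp = evoked(
                np.full(config.n_trials, config.short_hrf_fraction * config.hrf_amplitude)
            )
        physio_o = np.zeros(n)
        physio_r = np.zeros(n)
        for b in bands:
            amp = config.band_amplitudes[b]
            if amp == 0:
                continue
            lag = config.physio_hbr_lag_s.get(b, 0.0)
            arg = 2.0 * np.pi * freqs[b]
            physio_o += amp * np.sin(arg * (t - delays[b][c_idx]) + phases[b])
            physio_r += amp * np.sin(arg * (t - delays[b][c_idx] - lag) + phases[b])
        hbo[c_idx] = resp + physio_o
        hbr[c_idx] = -config.hbr_ratio * resp + config.physio_hbr_ratio * physio_r

    # forward Beer-Lambert to optical density, then intensities
    intensity = np.empty((len(channel_ids), 2, n))
    n_motion = rng.poisson(config.motion_rate * config.duration_s / 60.0)
    motion = np.zeros(n)
    motion_scale = rng.uniform(0.2, 1.0, size=len(channel_ids))
    for _ in range(n_motion):
        t0 = rng.uniform(0.0, config.duration_s)
        amp = rng.uniform(0.5, 1.5) * config.motion_amplitude_od * rng.choice([-1, 1])
        if rng.random() < 0.5:
            motion += amp * np.exp(-np.abs(t - t0) / 0.3)  # spike
        else:
            motion += amp * (t >= t0)  # step
    for c_idx, ch in enumerate(mont.channels):
        od = mbll_forward(
            hbo[c_idx], hbr[c_idx], ch.wavelengths, ch.separation_cm
        )
        od = od + motion_scale[c_idx] * motion
        od = od + rng.normal(0.0, config.od_noise_sd, size=od.shape)
        base = config.baseline_intensity * rng.uniform(0.5, 2.0, size=(2, 1))
        intensity[c_idx] = base * np.exp(-od)

    return RawRecording(
        montage=mont,
        channel_ids=channel_ids,
        intensity=intensity,
        fs=config.fs,
        events=onsets,
        task_s=config.task_s,
        participant_id=truth.participant_ids[i],
        lesion_side=lesion,
    )


# ---------------------------------------------------------------------------
# cohorts


def generate_sem_cohort(config: SimConfig):
    """Trial-level M1-LAT draws + item responses, skipping the optics.

    Returns (m1lat, items, truth) where ``m1lat`` has shape
    (participants, trials, 8): the true per-pair mean plus Student-t
    trial noise — the quantity the laterality stage would deliver from
    noise-free recordings.
    """
    root = np.random.SeedSequence(config.seed)
    rng_truth, rng_items, rng_trials = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    truth = _draw_truth(config, rng_truth)
    items = _draw_items(truth, rng_items)
    m1lat = np.stack(
        [
            truth.m1lat_mean[i][None, :]
            + _draw_trial_noise(config, rng_trials, truth.noise_sd[i])
            for i in range(config.n_participants)
        ]
    )
    return m1lat, items, truth


def generate_cohort(config: SimConfig):
    """Full cohort: raw recordings + item responses + stored truth."""
    root = np.random.SeedSequence(config.seed)
    rng_truth, rng_items, rng_trials, *rec_seeds = root.spawn(
        3 + config.n_participants
    )
    truth = _draw_truth(config, np.random.default_rng(rng_truth))
    items = _draw_items(truth, np.random.default_rng(rng_items))
    rng_tr = np.random.default_rng(rng_trials)
    mont = build_montage()
    recordings = [
        generate_recording(
            config,
            truth,
            i,
            np.random.default_rng(rec_seeds[i]),
            montage=mont,
            trial_noise=_draw_trial_noise(config, rng_tr, truth.noise_sd[i]),
        )
        for i in range(config.n_participants)
    ]
    return recordings, items, truth
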