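"""Synthetic spinal-cord resting-state phantom with known ground truth.

The phantom emulates an axial cervical-cord acquisition: a butterfly of
gray matter (two ventral and two dorsal horns joined by a central band)
inside a white-matter ellipse, surrounded by a CSF annulus and neck
tissue.  Planted low-frequency signals are shared between left/right
ventral horns (correlation ``rho_vv``) and between left/right dorsal
horns (``rho_dd``); quasi-periodic cardiac and respiratory confounds are
strongest in CSF; slice-wise bulk intensity events mimic swallowing; slow
in-plane translations and thermal noise complete the noise model.

Neural signals are synthesized as sums of random-phase sinusoids on the
DFT frequency grid inside the configured signal band; the shared
components are orthonormalized in-sample so coupled pairs realize their
configured correlation exactly, while uncoupled pairs keep genuine
sampling dispersion.  The correlations actually planted in each
realization are recorded in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fourier
from ._utils import fast_copy
from .core import Volume4D, volume_times
from .masks import ROI_NAMES, TissueMasks

TISSUES = ("gm", "wm", "csf", "neck")


class PhantomConfigError(ValueError):
    """Raised for invalid phantom configurations."""


def _tissue_map(value, default: dict[str, float]) -> dict[str, float]:
    out = dict(default)
    if value is not None:
        out.update(value)
    bad = [t for t, v in out.items() if v < 0]
    if bad:
        raise PhantomConfigError(f"negative tissue amplitude for {bad}")
    return out


@dataclass
class PhantomConfig:
    """Configuration of the synthetic cord phantom.

    Defaults describe the acquisition being emulated (12 slices of 150
    volumes at TR 3.6 s on a 64 x 64 in-plane grid) and a physiological-
    noise-dominated 7 T noise regime; amplitudes are arbitrary intensity
    units on a tissue baseline of order 1000.
    """

    nx: int = 64
    ny: int = 64
    n_slices: int = 12
    n_volumes: int = 150
    tr: float = 3.6
    voxel_size: tuple[float, float, float] = (0.31, 0.31, 4.0)

    # planted connectivity
    rho_vv: float = 0.5
    rho_dd: float = 0.35
    rho_vd: float = 0.0
    signal_band: tuple[float, float] = (0.01, 0.08)
    neural_amp: float = 12.0

    # noise model
    baselines: dict = None
    sigma_thermal: float = 25.0
    cardiac_freq: float = 1.05
    cardiac_amp: dict = None
    cardiac_phase_spread: float = 1.0       # rad, CSF pulse-wave lag spread
    resp_freq: float = 0.30
    resp_amp: dict = None
    physio_mod_depth: float = 0.05
    canal_amp: dict = None                  # slow cord-canal fluctuation
    csf_flow_amp: float = 10.0
    n_csf_flow: int = 2
    neck_structured_amp: float = 12.0
    n_neck_structured: int = 3
    bulk_rate: float = 2.0
    bulk_amp: float = 0.12

    # motion
    motion_drift_amp: float = 1.0
    motion_jump_prob: float = 0.0
    motion_jump_amp: float = 1.5

    # physiological logging
    physio_fs: float = 50.0

    seed: int = 0

    # geometry (voxels); half-integer center keeps the phantom mirror
    # symmetric about the dividing axes
    wm_semiaxes: tuple[float, float] = (19.0, 13.0)
    csf_semiaxes: tuple[float, float] = (25.0, 18.0)
    neck_margin: int = 3

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.n_slices <= 0:
            raise PhantomConfigError("grid dimensions must be positive")
        if self.n_volumes < 20:
            raise PhantomConfigError("n_volumes must be >= 20")
        if self.tr <= 0:
            raise PhantomConfigError("tr must be positive")
        for name in ("rho_vv", "rho_dd", "rho_vd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomConfigError(f"{name}={v} outside [0, 1]")
        lo, hi = self.signal_band
        if not 0 <= lo < hi:
            raise PhantomConfigError("signal band must satisfy 0 <= lo < hi")
        if self.sigma_thermal < 0 or self.neural_amp < 0:
            raise PhantomConfigError("amplitudes must be >= 0")
        self.baselines = _tissue_map(
            self.baselines, {"gm": 1000.0, "wm": 900.0, "csf": 1100.0,
                             "neck": 800.0})
        self.cardiac_amp = _tissue_map(
            self.cardiac_amp, {"gm": 8.0, "wm": 6.0, "csf": 30.0,
                               "neck": 10.0})
        self.resp_amp = _tissue_map(
            self.resp_amp, {"gm": 6.0, "wm": 5.0, "csf": 18.0, "neck": 14.0})
        self.canal_amp = _tissue_map(
            self.canal_amp, {"gm": 18.0, "wm": 18.0, "csf": 25.0,
                             "neck": 0.0})

    def quiet(self, **overrides) -> "PhantomConfig":
        """A copy with all noise, confound and motion sources switched off."""
        zero = {t: 0.0 for t in TISSUES}
        kwargs = dict(
            sigma_thermal=0.0, cardiac_amp=zero, resp_amp=zero,
            canal_amp=zero, csf_flow_amp=0.0, neck_structured_amp=0.0,
            bulk_rate=0.0, motion_drift_amp=0.0, motion_jump_prob=0.0)
        kwargs.update(overrides)
        return self.replace(**kwargs)

    def replace(self, **overrides) -> "PhantomConfig":
        from dataclasses import asdict
        params = asdict(self)
        params.update(overrides)
        return PhantomConfig(**params)


@dataclass
class PhysioRecord:
    """Externally monitored cardiac and respiratory traces.

    ``cardiac`` and ``resp`` are sampled uniformly at ``fs`` Hz starting
    at t = 0; ``acq_times`` holds the acquisition time (s) of every
    (slice, volume) pair.
    """

    fs: float
    cardiac: np.ndarray
    resp: np.ndarray
    acq_times: np.ndarray                    # (n_slices, n_volumes)

    def __post_init__(self) -> None:
        self.cardiac = np.asarray(self.cardiac, dtype=np.float64)
        self.resp = np.asarray(self.resp, dtype=np.float64)
        self.acq_times = np.asarray(self.acq_times, dtype=np.float64)
        if self.cardiac.shape != self.resp.shape:
            raise ValueError("cardiac and resp traces differ in length")
        if self.acq_times.size:
            flat_ok = all(np.all(np.diff(row) > 0) for row in self.acq_times)
            if not flat_ok:
                raise ValueError("acquisition times must strictly increase")
            if self.cardiac.size and (
                    self.times[-1] < self.acq_times.max()):
                raise ValueError("physio traces do not cover the scan")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.cardiac.size) / self.fs


def slice_acquisition_times(n_slices: int, n_volumes: int,
                            tr: float) -> np.ndarray:
    """Acquisition time of each (slice, volume): slices spread over the TR."""
    v = np.arange(n_volumes) * tr
    s = np.arange(n_slices) * (tr / n_slices)
    return s[:, None] + v[None, :]


def write_physio(record: PhysioRecord, path) -> None:
    """Write the physio traces as a TSV with columns time, cardiac, resp."""
    if record.cardiac.shape != record.resp.shape:
        raise ValueError("cardiac and resp traces differ in length")
    df = pd.DataFrame({"time": record.times, "cardiac": record.cardiac,
                       "resp": record.resp})
    df.to_csv(path, sep="\t", index=False)


def read_physio(path, acq_times=None) -> PhysioRecord:
    """Read a physio TSV written by :func:`write_physio`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["time"].to_numpy()
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 50.0
    if acq_times is None:
        acq_times = np.empty((0, 0))
    return PhysioRecord(fs=fs, cardiac=df["cardiac"].to_numpy(),
                        resp=df["resp"].to_numpy(),
                        acq_times=np.asarray(acq_times, dtype=np.float64))


@dataclass
class GroundTruth:
    """Everything planted in the phantom, for downstream verification."""

    planted: np.ndarray                      # (n_slices, 8, 8)
    translations: np.ndarray                 # (n_slices, n_volumes, 2) voxels
    components: dict[str, np.ndarray] = field(default_factory=dict)
    roi_names: tuple = ROI_NAMES

    def __post_init__(self) -> None:
        self.planted = np.asarray(self.planted, dtype=np.float64)
        self.translations = np.asarray(self.translations, dtype=np.float64)
        for m in self.planted:
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ValueError("planted matrix must be symmetric with "
                                 "unit diagonal")

    def save(self, path) -> None:
        payload = {
            "roi_names": list(self.roi_names),
            "planted": self.planted.tolist(),
            "translations": self.translations.tolist(),
            "components": {k: np.asarray(v).tolist()
                           for k, v in self.components.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(planted=np.array(payload["planted"]),
                   translations=np.array(payload["translations"]),
                   components={k: np.array(v)
                               for k, v in payload["components"].items()},
                   roi_names=tuple(payload["roi_names"]))


# ---------------------------------------------------------------------------
# geometry

def _ellipse(xx, yy, cx, cy, ax, ay):
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def build_geometry(cfg: PhantomConfig):
    """Analytic butterfly geometry on one slice.

    Returns the tissue masks plus per-horn GM masks (LV/RV/LD/RD and the
    central band) used to paint neural signals.
    """
    nx, ny = cfg.nx, cfg.ny
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0   # half-integer for even grids
    xx, yy = np.mgrid[0:nx, 0:ny].astype(float)

    wm_ell = _ellipse(xx, yy, cx, cy, *cfg.wm_semiaxes)
    csf_ell = _ellipse(xx, yy, cx, cy, *cfg.csf_semiaxes)
    moat_ell = _ellipse(xx, yy, cx, cy, cfg.csf_semiaxes[0] + cfg.neck_margin,
                        cfg.csf_semiaxes[1] + cfg.neck_margin)

    # horns: ventral wider than dorsal, mirror symmetric left-right;
    # positions and sizes scale with the white-matter ellipse so the
    # butterfly keeps its proportions at any cord size
    ax, ay = cfg.wm_semiaxes
    horns = {}
    horns["LV"] = _ellipse(xx, yy, cx + 0.45 * ax, cy - 0.38 * ay,
                           0.23 * ax, 0.48 * ay)
    horns["RV"] = _ellipse(xx, yy, cx - 0.45 * ax, cy - 0.38 * ay,
                           0.23 * ax, 0.48 * ay)
    horns["LD"] = _ellipse(xx, yy, cx + 0.33 * ax, cy + 0.46 * ay,
                           0.18 * ax, 0.46 * ay)
    horns["RD"] = _ellipse(xx, yy, cx - 0.33 * ax, cy + 0.46 * ay,
                           0.18 * ax, 0.46 * ay)
    central = ((np.abs(xx - cx) <= max(1.5, 0.11 * ax))
               & (np.abs(yy - cy) <= 0.55 * ay))
    for k in horns:
        horns[k] &= wm_ell
    central &= wm_ell
    gm = central.copy()
    for m in horns.values():
        gm |= m
    # horn masks are made exclusive of the central band and of each other
    # (ventral takes precedence on the rare overlap voxel)
    claimed = central.copy()
    for k in ("LV", "RV", "LD", "RD"):
        horns[k] = horns[k] & ~claimed
        claimed |= horns[k]

    wm = wm_ell & ~gm
    csf = csf_ell & ~wm_ell
    neck = ~moat_ell
    moat = moat_ell & ~csf_ell
    return {"gm": gm, "wm": wm, "csf": csf, "neck": neck, "moat": moat,
            "horns": horns, "central": central, "center": (cx, cy)}


# ---------------------------------------------------------------------------
# signal synthesis

def band_limited_series(rng: np.random.Generator, n: int, tr: float,
                        band: tuple[float, float], n_series: int = 1,
                        ) -> np.ndarray:
    """Random-phase sinusoids on the DFT grid inside ``band`` (columns).

    Each column is zero-mean with unit sample variance (ddof=0).  All
    power lies exactly on in-band DFT frequencies, so periodograms place
    100% of the power inside the band.
    """
    lo, hi = band
    df = 1.0 / (n * tr)
    k_lo = max(1, int(np.ceil(lo / df - 1e-9)))
    k_hi = int(np.floor(hi / df + 1e-9))
    k_hi = min(k_hi, n // 2 - 1)
    if k_hi < k_lo:
        raise PhantomConfigError(
            f"band {band} contains no DFT frequencies at n={n}, tr={tr}")
    k = np.arange(k_lo, k_hi + 1)
    t = np.arange(n)[:, None]
    out = np.empty((n, n_series))
    for j in range(n_series):
        phases = rng.uniform(0, 2 * np.pi, size=k.size)
        amps = rng.uniform(0.5, 1.0, size=k.size)
        x = (amps * np.cos(2 * np.pi * k * t / n + phases)).sum(axis=1)
        out[:, j] = x
    out -= out.mean(axis=0)
    out /= out.std(axis=0)
    return out


def _horn_signals(rng, cfg: PhantomConfig):
    """Unit-variance horn time courses with the planted correlations.

    The shared ventral/dorsal signals are exactly sample-orthonormal and
    each horn's independent component is exactly orthogonal to both, so
    the expected correlation of a coupled pair equals the configured rho
    precisely.  The four independent components are *not* orthogonalized
    against each other: uncoupled horn pairs keep genuine Fisher-null
    sampling dispersion (~(1-rho)/sqrt(n)), as independent signals
    would.  The realized correlations are recorded in the ground truth.
    """
    raw = band_limited_series(rng, cfg.n_volumes, cfg.tr,
                              cfg.signal_band, 6)
    q, _ = np.linalg.qr(raw[:, :2])
    q *= np.sign(q[0, :] + (q[0, :] == 0)) * np.sqrt(cfg.n_volumes)
    sv = q[:, 0]
    sd = cfg.rho_vd * q[:, 0] + np.sqrt(1 - cfg.rho_vd ** 2) * q[:, 1]
    indep = []
    for j in range(2, 6):
        e = raw[:, j]
        e = e - q @ (q.T @ e) / cfg.n_volumes
        e = e / e.std()
        indep.append(e)
    a_v, b_v = np.sqrt(cfg.rho_vv), np.sqrt(1 - cfg.rho_vv)
    a_d, b_d = np.sqrt(cfg.rho_dd), np.sqrt(1 - cfg.rho_dd)
    horns = {
        "LV": a_v * sv + b_v * indep[0],
        "RV": a_v * sv + b_v * indep[1],
        "LD": a_d * sd + b_d * indep[2],
        "RD": a_d * sd + b_d * indep[3],
    }
    return sv, sd, horns


def expected_matrix(cfg: PhantomConfig) -> np.ndarray:
    """The 8x8 correlation matrix the construction targets in
    expectation (GM block only; WM sub-regions carry no planted
    signal)."""
    m = np.eye(8)
    m[0, 1] = m[1, 0] = cfg.rho_vv
    m[2, 3] = m[3, 2] = cfg.rho_dd
    vd = cfg.rho_vd * np.sqrt(cfg.rho_vv * cfg.rho_dd)
    for i in (0, 1):
        for j in (2, 3):
            m[i, j] = m[j, i] = vd
    return m


def realized_matrix(horns: dict[str, np.ndarray]) -> np.ndarray:
    """The 8x8 matrix of correlations actually planted in this
    realization (coupled pairs match the configuration exactly;
    uncoupled pairs carry their sampling fluctuation)."""
    m = np.eye(8)
    gm = np.corrcoef(np.stack([horns[k] for k in ("LV", "RV", "LD", "RD")]))
    m[:4, :4] = gm
    return m


def _slow_series(rng, n, tr, n_series=1, band=(0.002, 0.02)):
    hi = min(band[1], 0.45 / tr)
    try:
        return band_limited_series(rng, n, tr, (band[0], hi), n_series)
    except PhantomConfigError:
        return np.zeros((n, n_series))


def _cardiac_phase(rng, t_hi, freq):
    """Unwrapped cardiac phase with slow heart-rate variability."""
    n = t_hi.size
    slow = _slow_series(rng, n, t_hi[1] - t_hi[0], 1, (0.005, 0.05))[:, 0]
    inst = freq * (1.0 + 0.04 * slow / max(1e-9, np.abs(slow).max()))
    dt = np.diff(t_hi, prepend=0.0)
    return 2 * np.pi * np.cumsum(inst * dt)


def generate_phantom(cfg: PhantomConfig):
    """Generate the phantom.

    Returns
    -------
    (Volume4D, TissueMasks, PhysioRecord, GroundTruth)
        The volume is motion-free; apply :func:`render_motion` with the
        returned ground truth to add the planted translations.
    """
    rng = np.random.default_rng(cfg.seed)
    geo = build_geometry(cfg)
    n, ns = cfg.n_volumes, cfg.n_slices
    t_vol = volume_times(n, cfg.tr)
    acq = slice_acquisition_times(ns, n, cfg.tr)

    # --- neural signals -------------------------------------------------
    sv, sd, horns = _horn_signals(rng, cfg)

    # --- physio traces at high rate ------------------------------------
    duration = acq.max() + cfg.tr
    t_hi = np.arange(0.0, duration, 1.0 / cfg.physio_fs)
    phi_c_hi = _cardiac_phase(rng, t_hi, cfg.cardiac_freq)
    phi_r_hi = _cardiac_phase(rng, t_hi, cfg.resp_freq)
    cardiac_trace = np.exp(4.0 * (np.cos(phi_c_hi) - 1.0))   # pulse waveform
    resp_trace = np.cos(phi_r_hi)
    physio = PhysioRecord(fs=cfg.physio_fs, cardiac=cardiac_trace,
                          resp=resp_trace, acq_times=acq)

    # physio confounds at slice acquisition times.  The unmodulated part
    # lies in the order-2 Fourier span of the phase (removable by
    # RETROICOR); a slow amplitude modulation rides on top.  CSF pulsation
    # carries an azimuthally varying pulse-wave lag, making the CSF
    # cardiac component rank-2 rather than rank-1.
    phi_c = np.interp(acq, t_hi, phi_c_hi)                   # (ns, n)
    phi_r = np.interp(acq, t_hi, phi_r_hi)
    mod_c = 1.0 + cfg.physio_mod_depth * _slow_series(rng, n, cfg.tr,
                                                      1)[:, 0]
    mod_r = 1.0 + cfg.physio_mod_depth * _slow_series(rng, n, cfg.tr,
                                                      1)[:, 0]
    card_cos = (np.cos(phi_c) + 0.3 * np.cos(2 * phi_c)) * mod_c[None, :]
    card_sin = (np.sin(phi_c) + 0.3 * np.sin(2 * phi_c)) * mod_c[None, :]
    resp_conf = (np.cos(phi_r) + 0.5 * np.sin(2 * phi_r)) * mod_r[None, :]

    # --- slow cord-canal fluctuation, orthogonal to the neural basis ----
    g = _slow_series(rng, n, cfg.tr, 1, band=(0.005, 0.05))[:, 0]
    neural_stack = np.column_stack([sv, sd] + [horns[k] for k in horns])
    coef, *_ = np.linalg.lstsq(neural_stack, g, rcond=None)
    g = g - neural_stack @ coef
    sd_g = g.std()
    if sd_g > 0:
        g = g / sd_g

    # --- compartment-specific structured noise ---------------------------
    flows = _slow_series(rng, n, cfg.tr, cfg.n_csf_flow,
                         band=(0.004, 0.06)) if cfg.n_csf_flow else None
    necks = (band_limited_series(rng, n, cfg.tr, (0.004, 0.12),
                                 cfg.n_neck_structured)
             if cfg.n_neck_structured else None)

    # --- bulk (swallow) events ------------------------------------------
    bulk = np.zeros((ns, n))
    n_events = rng.poisson(cfg.bulk_rate)
    for _ in range(n_events):
        v0 = int(rng.integers(0, n))
        dur = int(rng.integers(1, 3))
        scale = rng.uniform(0.8, 1.2, size=ns)
        bulk[:, v0:v0 + dur] += cfg.bulk_amp * scale[:, None]

    # --- motion ----------------------------------------------------------
    trans = np.zeros((ns, n, 2))
    if cfg.motion_drift_amp > 0:
        drift = _slow_series(rng, n, cfg.tr, 2, band=(0.001, 0.01))
        peak = np.abs(drift).max(axis=0)
        drift = drift / np.where(peak > 0, peak, 1.0) * cfg.motion_drift_amp
        slice_scale = rng.uniform(0.9, 1.1, size=ns)
        trans += slice_scale[:, None, None] * drift[None, :, :]
    if cfg.motion_jump_prob > 0:
        jumps = rng.random((ns, n)) < cfg.motion_jump_prob
        mags = rng.uniform(-cfg.motion_jump_amp, cfg.motion_jump_amp,
                           size=(ns, n, 2))
        trans += jumps[:, :, None] * mags

    # --- assemble the volume ---------------------------------------------
    # every structured component is an outer product of a spatial profile
    # and a time course, so each slice is a single (n_vox x K) @ (K x n)
    # matrix product plus the neural horn signals and thermal noise
    nx, ny = cfg.nx, cfg.ny
    regions = {"gm": geo["gm"], "wm": geo["wm"], "csf": geo["csf"],
               "neck": geo["neck"] | geo["moat"]}
    base_img = np.zeros((nx, ny))
    card_amp_img = np.zeros((nx, ny))
    resp_amp_img = np.zeros((nx, ny))
    canal_img = np.zeros((nx, ny))
    for t_name in ("gm", "wm", "csf", "neck"):
        m = regions[t_name]
        base_img[m] = cfg.baselines[t_name]
        card_amp_img[m] = cfg.cardiac_amp[t_name]
        resp_amp_img[m] = cfg.resp_amp[t_name]
        canal_img[m] = cfg.canal_amp[t_name]

    xx, yy = np.mgrid[0:nx, 0:ny].astype(float)
    cx, cy = geo["center"]
    azim = np.arctan2(yy - cy, xx - cx)
    psi = np.where(geo["csf"], cfg.cardiac_phase_spread * np.sin(azim), 0.0)

    def _smooth_gain(mask, dc: float = 0.0):
        # smooth spatially-varying profile over a compartment; dc > 0
        # adds a uniform part (amplitude modulation rather than a
        # zero-mean pattern)
        k1, k2 = rng.uniform(0.5, 2.0, 2) * rng.choice([-1.0, 1.0], 2)
        theta = rng.uniform(0, 2 * np.pi)
        prof = dc + np.sin(2 * np.pi * (k1 * xx + k2 * yy) / nx + theta)
        return np.where(mask, prof, 0.0)

    # neck physiological amplitudes vary spatially (vessels and moving
    # anterior tissue), keeping the bulk / cardiac / respiratory
    # components spatially distinct so compartment PCA can resolve them
    neck = regions["neck"]
    card_img = np.where(neck, card_amp_img * _smooth_gain(neck, dc=1.5)
                        / 1.5, card_amp_img)
    resp_img = np.where(neck, resp_amp_img * _smooth_gain(neck, dc=1.5)
                        / 1.5, resp_amp_img)

    spatial = [base_img, card_img * np.cos(psi),
               -card_img * np.sin(psi), resp_img, canal_img]
    shared_rows = [g]

    # structured-noise amplitudes decay geometrically across components,
    # giving the compartment PCA spectra a realistic decaying profile
    if flows is not None:
        for j in range(cfg.n_csf_flow):
            amp = cfg.csf_flow_amp * 1.3 * 0.6 ** j
            spatial.append(amp * _smooth_gain(geo["csf"]))
            shared_rows.append(flows[:, j])
    if necks is not None:
        for j in range(cfg.n_neck_structured):
            amp = cfg.neck_structured_amp * (1.58, 0.73, 0.54)[j % 3]
            spatial.append(amp * _smooth_gain(regions["neck"]))
            shared_rows.append(necks[:, j])

    u = np.stack(spatial, axis=-1).reshape(nx * ny, -1)      # (n_vox, K)
    shared_v = np.stack(shared_rows)                         # (K-4, n)

    data = np.empty((nx, ny, ns, n))
    buf = np.empty((nx * ny, n))
    nbuf = np.empty((nx * ny, n)) if cfg.sigma_thermal > 0 else None
    horn_series = {k: cfg.neural_amp * horns[k] for k in horns}
    for s in range(ns):
        v = np.concatenate([np.stack([1.0 + bulk[s], card_cos[s],
                                      card_sin[s], resp_conf[s]]),
                            shared_v])
        np.matmul(u, v, out=buf)
        if nbuf is not None:
            rng.standard_normal(out=nbuf)
            np.multiply(nbuf, cfg.sigma_thermal, out=nbuf)
            np.add(buf, nbuf, out=buf)
        sl = data[:, :, s, :]
        np.copyto(sl, buf.reshape(nx, ny, n))
        for k, horn_mask in geo["horns"].items():
            sl[horn_mask] += horn_series[k]

    volume = Volume4D(data, cfg.voxel_size, cfg.tr)
    tile = lambda m: np.repeat(m[:, :, None], ns, axis=2)
    masks = TissueMasks(gm=tile(geo["gm"]), wm=tile(geo["wm"]),
                        csf=tile(geo["csf"]), not_spine=tile(geo["neck"]),
                        voxel_size=cfg.voxel_size)
    truth = GroundTruth(
        planted=np.repeat(realized_matrix(horns)[None], ns, axis=0),
        translations=trans,
        components={
            "shared_ventral": sv, "shared_dorsal": sd,
            "lv": horns["LV"], "rv": horns["RV"],
            "ld": horns["LD"], "rd": horns["RD"],
            "canal": g, "bulk": bulk,
            "cardiac_cos": card_cos, "cardiac_sin": card_sin,
            "resp_confound": resp_conf,
        })
    return volume, masks, physio, truth


def render_motion(volume: Volume4D, truth: GroundTruth) -> Volume4D:
    """Apply the planted per-slice translations with sinc interpolation.

    Zero translations return a bit-identical copy.
    """
    trans = truth.translations
    if trans.shape[:2] != (volume.n_slices, volume.n_volumes):
        raise ValueError("translation trace does not match the volume")
    nx, ny = volume.shape[:2]
    if np.abs(trans).max() > min(nx, ny) / 4.0:
        raise ValueError("planted translation exceeds 1/4 of the grid "
                         "extent; phantom misconfigured")
    out = fast_copy(volume.data)
    for s in range(volume.n_slices):
        if not np.any(trans[s]):
            continue
        stack = np.moveaxis(volume.data[:, :, s, :], -1, 0)   # (n, nx, ny)
        shifted = _fourier.shift_stack(stack, trans[s])
        out[:, :, s, :] = np.moveaxis(shifted, 0, -1)
    return Volume4D(out, volume.voxel_size, volume.tr)
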