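"""Synthetic paired (patch, 12-lead) ECG generator.

Both channel groups are projections of one cardiac-dipole trajectory, so the
physics that makes reduced-lead reconstruction possible — a common 3-D source
seen through different lead fields — is built in.  The dipole is a sum of
Gaussian waves (P, Q, R, S, T) over a cyclic beat phase, in the style of the
classic dynamical ECG generators, which gives every beat analytic, exactly
known fiducial times (wave center ± 3·width) to score delineation against.

The three patch channels are bipolar leads from a small left-upper-chest
area: they see the frontal (x, y) dipole components at full strength but the
anterior–posterior (z) component attenuated by a factor ``kappa``, emulating
the reduced horizontal-plane information of a patch device.  An optional
saturating nonlinearity and additive noise give the nonlinear reconstruction
model something a purely linear map cannot capture.

Axes: x = horizontal (toward the subject's left), y = vertical (down),
z = anterior.  Dipole units are arbitrary; ``GAIN_UV`` converts a unit
projection to microvolts and is chosen so the default lead II R wave is
about 1 mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .records import MultiLeadRecord, PATCH_LEADS, STANDARD_LEADS

WAVES = ("P", "Q", "R", "S", "T")

#: μV per dipole unit after lead-field projection.
GAIN_UV = 1000.0

#: Scale (μV) of the tanh saturation used for the optional nonlinearity.
NONLIN_SCALE_UV = 400.0

#: Cosine ramp length (s) at either end of the ST plateau.
ST_RAMP_S = 0.020

#: Beats whose R peak falls closer than this to the record end are neither
#: rendered nor listed in the ground truth (QRS truncation makes them
#: undetectable in principle).
EDGE_MARGIN_S = 0.25

PATHOLOGY_KINDS = ("wide_qrs", "st_elevation", "st_depression",
                   "pathologic_q", "t_inversion", "ectopic", "none")


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# morphology

@dataclass
class BeatMorphology:
    """Gaussian-sum parameterization of one beat.

    ``centers[w]`` is the angular position of wave ``w`` on the beat cycle
    [0, 2π) with the R peak at π; ``widths[w]`` the Gaussian width in
    radians; ``amps[w]`` the signed 3-vector amplitude (dipole units) along
    (x, y, z).  ``st_offset`` shifts the ST plateau (S offset to T onset) in
    mV as seen in lead II.
    """

    centers: dict
    widths: dict
    amps: dict
    heart_rate: float = 60.0
    st_offset: float = 0.0

    def __post_init__(self):
        self.amps = {w: np.asarray(self.amps[w], dtype=float) for w in WAVES}
        for w in WAVES:
            if not self.widths[w] > 0:
                raise SynthConfigError(f"width of {w} must be positive")
        order = [self.centers[w] for w in WAVES]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise SynthConfigError("wave centers must be ordered P<Q<R<S<T")
        if not 30.0 <= self.heart_rate <= 200.0:
            raise SynthConfigError("heart_rate must be in [30, 200] bpm")

    # Analytic fiducials (phase units); onset/offset = center ± 3·width.
    def onset(self, w: str) -> float:
        return self.centers[w] - 3.0 * self.widths[w]

    def offset(self, w: str) -> float:
        return self.centers[w] + 3.0 * self.widths[w]

    def qrs_duration_s(self) -> float:
        """Analytic QRS duration (Q onset to S offset) in seconds."""
        span = self.offset("S") - self.onset("Q")
        return span / (2.0 * np.pi) * 60.0 / self.heart_rate

    def pr_interval_s(self) -> float:
        span = self.onset("Q") - self.onset("P")
        return span / (2.0 * np.pi) * 60.0 / self.heart_rate

    def qt_interval_s(self) -> float:
        span = self.offset("T") - self.onset("Q")
        return span / (2.0 * np.pi) * 60.0 / self.heart_rate


def default_morphology(heart_rate: float = 60.0) -> BeatMorphology:
    """Normal sinus morphology: QRS ≈ 95 ms, PR ≈ 160 ms, QT ≈ 385 ms at
    60 bpm.

    Wave timing is specified in seconds and converted to beat phase, so P
    and QRS durations stay rate-independent while the T wave (hence QT)
    shortens with √RR as real repolarization does; the T offset is clamped
    to 47% of the cycle after R so fast rates keep T inside the beat.
    """
    omega = 2.0 * np.pi * heart_rate / 60.0  # rad per second
    f_t = np.sqrt(60.0 / heart_rate)
    # T onset ≈155 ms after R at 60 bpm: leaves a flat ST segment under the
    # J+80 ms measurement point
    t_t, b_t = 0.260 * f_t, 0.035 * f_t
    limit = 0.47 * 60.0 / heart_rate
    if t_t + 3.0 * b_t > limit:
        s = limit / (t_t + 3.0 * b_t)
        t_t *= s
        b_t *= s
    pi = np.pi
    return BeatMorphology(
        centers={"P": pi - 0.16715 * omega, "Q": pi - 0.028648 * omega,
                 "R": pi, "S": pi + 0.028648 * omega, "T": pi + t_t * omega},
        widths={"P": 0.014324 * omega, "Q": 0.0071620 * omega,
                "R": 0.0095493 * omega, "S": 0.0063662 * omega,
                "T": b_t * omega},
        amps={"P": (0.09, 0.13, 0.10),
              "Q": (-0.05, -0.08, -0.06),
              "R": (0.70, 0.70, 0.35),
              "S": (-0.08, -0.12, -0.16),
              "T": (0.20, 0.28, 0.18)},
        heart_rate=heart_rate,
    )


def ectopic_morphology(heart_rate: float = 60.0) -> BeatMorphology:
    """Ventricular ectopic beat: no P wave, wide (~140 ms) QRS with a
    rotated axis, inverted T."""
    base = default_morphology(heart_rate)
    f = 0.140 / base.qrs_duration_s()
    pi = np.pi
    centers = dict(base.centers)
    widths = dict(base.widths)
    for w in ("Q", "R", "S"):
        centers[w] = pi + f * (base.centers[w] - pi)
        widths[w] = f * base.widths[w]
    return BeatMorphology(
        centers=centers, widths=widths,
        amps={"P": (0.0, 0.0, 0.0),
              "Q": (0.10, -0.06, 0.15),
              "R": (-0.25, 1.05, -0.65),
              "S": (0.12, -0.20, 0.25),
              "T": (-0.23, -0.39, -0.23)},
        heart_rate=heart_rate,
    )


# Fixed dipole direction of the ST plateau, normalized so lead II sees
# exactly ``st_offset`` mV (computed below once the lead field exists).
_ST_DIRECTION_RAW = np.array([0.70, 0.70, 0.35])


# --------------------------------------------------------------------------
# lead fields

@dataclass
class LeadField:
    """Projection matrix from the 3-D dipole to lead voltages."""

    lead_names: tuple
    matrix: np.ndarray  # (n_leads, 3)

    def __post_init__(self):
        self.lead_names = tuple(self.lead_names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.lead_names), 3):
            raise SynthConfigError("lead field must be (n_leads, 3)")


def standard12_leadfield() -> LeadField:
    """The 12 standard rows; limb/augmented rows obey the Einthoven and
    Goldberger identities by construction (III = II − I, aVR = −(I+II)/2,
    aVL = I − II/2, aVF = II − I/2)."""
    I = np.array([1.0, 0.0, 0.0])
    II = np.array([0.5, 0.866, 0.0])
    rows = [I, II, II - I, -(I + II) / 2.0, I - II / 2.0, II - I / 2.0,
            [-0.2, 0.1, 1.0], [0.0, 0.1, 1.1], [0.3, 0.15, 0.9],
            [0.6, 0.2, 0.7], [0.85, 0.2, 0.4], [1.0, 0.2, 0.15]]
    return LeadField(STANDARD_LEADS, np.vstack([np.asarray(r, float) for r in rows]))


def patch_leadfield(kappa: float = 0.3) -> LeadField:
    """Three bipolar patch rows; the anterior (z) column is attenuated by
    ``kappa`` to model the patch's weak view of horizontal-plane components.
    Rows are linearly independent for any kappa > 0."""
    if not 0.0 <= kappa <= 1.0:
        raise SynthConfigError("kappa must be in [0, 1]")
    rows = np.array([[1.0, 0.2, 0.8],
                     [0.1, 1.0, 0.5],
                     [0.6, -0.7, 1.0]])
    rows = rows.copy()
    rows[:, 2] *= kappa
    return LeadField(PATCH_LEADS, rows)


_STD = standard12_leadfield()
_II_ROW = _STD.matrix[list(STANDARD_LEADS).index("II")]
#: dipole vector that produces +1 mV (GAIN_UV μV · 1e-3) in lead II
ST_DIRECTION = _ST_DIRECTION_RAW / float(_II_ROW @ _ST_DIRECTION_RAW)


# --------------------------------------------------------------------------
# pathology

@dataclass
class PathologySpec:
    """A morphology perturbation that makes the paper's printed criteria
    pass or fail by a controlled margin.

    magnitude semantics: wide_qrs → target QRS duration (ms);
    st_elevation / st_depression → |ST offset| (mV); pathologic_q → Q depth
    as a fraction of R; t_inversion / ectopic / none → unused.
    beat_indices applies to ectopic beats only; other kinds act on every
    beat.
    """

    kind: str
    magnitude: float = 0.0
    beat_indices: tuple = ()

    def __post_init__(self):
        if self.kind not in PATHOLOGY_KINDS:
            raise SynthConfigError(f"unknown pathology kind {self.kind!r}")
        if self.kind == "wide_qrs" and not 0.0 < self.magnitude <= 200.0:
            raise SynthConfigError("wide_qrs magnitude is QRS ms, must be in (0, 200]")
        if self.kind in ("st_elevation", "st_depression") and not \
                0.0 <= self.magnitude <= 0.5:
            raise SynthConfigError("|ST offset| must be ≤ 0.5 mV")
        self.beat_indices = tuple(int(i) for i in self.beat_indices)


def apply_pathology(morphology: BeatMorphology,
                    spec: PathologySpec) -> BeatMorphology:
    """Return the morphology of one affected beat under ``spec``.

    ``none`` returns an identical copy.  ``wide_qrs`` scales the Q/R/S
    centers' offsets from R and their widths by a common factor so that the
    analytic QRS duration equals ``magnitude`` ms exactly.  ``pathologic_q``
    sets the Q amplitude to −magnitude·a_R and widens Q to ≥50 ms so the
    duration half of the printed criterion is met and detection hinges on
    depth.  ``ectopic`` substitutes the fixed ectopic morphology.
    """
    m = replace(morphology,
                centers=dict(morphology.centers),
                widths=dict(morphology.widths),
                amps={w: morphology.amps[w].copy() for w in WAVES})
    if spec.kind == "none":
        return m
    if spec.kind == "wide_qrs":
        f = (spec.magnitude / 1000.0) / morphology.qrs_duration_s()
        pi = np.pi
        for w in ("Q", "R", "S"):
            m.centers[w] = pi + f * (morphology.centers[w] - pi)
            m.widths[w] = f * morphology.widths[w]
        return m
    if spec.kind == "st_elevation":
        m.st_offset = spec.magnitude
        return m
    if spec.kind == "st_depression":
        m.st_offset = -spec.magnitude
        return m
    if spec.kind == "pathologic_q":
        m.amps["Q"] = -spec.magnitude * morphology.amps["R"]
        min_b = (0.050 * morphology.heart_rate / 60.0) * 2.0 * np.pi / 6.0
        m.widths["Q"] = max(morphology.widths["Q"], min_b)
        return m
    if spec.kind == "t_inversion":
        m.amps["T"] = -morphology.amps["T"]
        return m
    if spec.kind == "ectopic":
        return ectopic_morphology(morphology.heart_rate)
    raise SynthConfigError(f"unknown pathology kind {spec.kind!r}")


# --------------------------------------------------------------------------
# ground truth

FIDUCIAL_KEYS = ("p_on", "p_peak", "p_off", "qrs_on", "q_peak", "r_peak",
                 "s_peak", "qrs_off", "t_on", "t_peak", "t_off")


@dataclass
class GroundTruthBeat:
    """Analytic per-beat truth: R time, fiducial times (s) and label."""

    r_time: float
    fiducials: dict
    label: str = "normal"


def _beat_ground_truth(morph: BeatMorphology, t0: float, rr: float,
                       label: str) -> GroundTruthBeat:
    def to_time(theta):
        return t0 + theta / (2.0 * np.pi) * rr

    fid = {}
    has_p = float(np.abs(morph.amps["P"]).sum()) > 0
    fid["p_on"] = to_time(morph.onset("P")) if has_p else None
    fid["p_peak"] = to_time(morph.centers["P"]) if has_p else None
    fid["p_off"] = to_time(morph.offset("P")) if has_p else None
    fid["qrs_on"] = to_time(morph.onset("Q"))
    fid["q_peak"] = to_time(morph.centers["Q"])
    fid["r_peak"] = to_time(morph.centers["R"])
    fid["s_peak"] = to_time(morph.centers["S"])
    fid["qrs_off"] = to_time(morph.offset("S"))
    fid["t_on"] = to_time(morph.onset("T"))
    fid["t_peak"] = to_time(morph.centers["T"])
    fid["t_off"] = to_time(morph.offset("T"))
    return GroundTruthBeat(r_time=fid["r_peak"], fiducials=fid, label=label)


# --------------------------------------------------------------------------
# dipole synthesis

def _rr_sequence(heart_rate: float, duration: float, rr_jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    rr0 = 60.0 / heart_rate
    rrs = []
    t = 0.0
    while t < duration - 1e-12:
        jitter = 0.0
        if rr_jitter > 0:
            jitter = float(np.clip(rng.normal(0.0, rr_jitter), -3 * rr_jitter,
                                   3 * rr_jitter))
        rr = rr0 * (1.0 + jitter)
        rrs.append(rr)
        t += rr
    return np.asarray(rrs)


def _synth_dipole(per_beat, rr_seq, fs, n_samples):
    """Sum per-beat Gaussian waves into a (n_samples, 3) dipole."""
    d = np.zeros((n_samples, 3))
    t0 = 0.0
    for morph, rr in zip(per_beat, rr_seq):
        if t0 + 0.5 * rr >= n_samples / fs - EDGE_MARGIN_S:
            # R peak at the record edge: beat not reliably observable
            t0 += rr
            continue
        i0 = max(int(np.floor(t0 * fs)), 0)
        i1 = min(int(np.ceil((t0 + rr) * fs)) + 1, n_samples)
        if i0 >= i1:
            t0 += rr
            continue
        t = np.arange(i0, i1) / fs
        theta = (t - t0) / rr * 2.0 * np.pi
        seg = np.zeros((i1 - i0, 3))
        for w in WAVES:
            a = morph.amps[w]
            if not np.any(a):
                continue
            g = np.exp(-0.5 * ((theta - morph.centers[w]) / morph.widths[w]) ** 2)
            seg += g[:, None] * a[None, :]
        if morph.st_offset != 0.0:
            # the shift spans the whole ST–T complex (as ischemic deviation
            # does), so the J+80 ms measurement point sits on the plateau
            lo = morph.offset("S")
            hi = morph.offset("T")
            ramp = ST_RAMP_S / rr * 2.0 * np.pi
            env = np.clip((theta - (lo - ramp)) / ramp, 0.0, 1.0) * \
                np.clip(((hi + ramp) - theta) / ramp, 0.0, 1.0)
            env = 0.5 - 0.5 * np.cos(np.pi * env)  # cosine-smoothed edges
            seg += (morph.st_offset * env)[:, None] * ST_DIRECTION[None, :]
        d[i0:i1] += seg
        t0 += rr
    return d


def make_dipole_trajectory(morphology: BeatMorphology, duration: float,
                           fs: float, rr_jitter: float = 0.0,
                           seed: int = 0):
    """Generate the dipole trajectory for a uniform-morphology recording.

    Returns ``(dipole, beats)`` where ``dipole`` is (n_samples, 3) and
    ``beats`` a list of :class:`GroundTruthBeat` with analytic fiducials
    (wave center ± 3·width mapped to time; R peak at mid-cycle, so at
    ``rr_jitter=0`` and 60 bpm the R times are 0.5 + k·1.0 s).
    """
    if fs <= 0 or duration <= 0:
        raise SynthConfigError("fs and duration must be positive")
    if duration < 2.0 * 60.0 / morphology.heart_rate:
        raise SynthConfigError("duration must cover at least 2 beats")
    rng = np.random.default_rng(seed)
    rr_seq = _rr_sequence(morphology.heart_rate, duration, rr_jitter, rng)
    n = int(round(duration * fs))
    dipole = _synth_dipole([morphology] * len(rr_seq), rr_seq, fs, n)
    beats = []
    t0 = 0.0
    for rr in rr_seq:
        b = _beat_ground_truth(morphology, t0, rr, "normal")
        if b.r_time < duration - EDGE_MARGIN_S:
            beats.append(b)
        t0 += rr
    return dipole, beats


# --------------------------------------------------------------------------
# projection

def project_leads(dipole: np.ndarray, leadfield: LeadField,
                  nonlinearity: float = 0.0, fs: float = 250.0,
                  subject: str = "") -> MultiLeadRecord:
    """Project the dipole through a lead field into a μV record.

    Each lead is ``g(row · d(t)) · GAIN_UV`` with
    ``g(u) = (1−λ)·u + λ·s0·tanh(u/s0)`` applied on the μV scale
    (s0 = ``NONLIN_SCALE_UV``); λ = 0 gives exact linearity.
    """
    dipole = np.asarray(dipole, dtype=float)
    if dipole.ndim != 2 or dipole.shape[1] != 3:
        raise ValueError("dipole must be (n_samples, 3)")
    if nonlinearity < 0:
        raise ValueError("nonlinearity must be ≥ 0")
    y = dipole @ leadfield.matrix.T * GAIN_UV
    if nonlinearity > 0:
        lam = nonlinearity
        y = (1.0 - lam) * y + lam * NONLIN_SCALE_UV * np.tanh(y / NONLIN_SCALE_UV)
    return MultiLeadRecord(lead_names=leadfield.lead_names, fs=fs, data=y,
                           subject=subject)


# --------------------------------------------------------------------------
# paired recordings

@dataclass
class SynthConfig:
    """Study conditions for one synthetic paired recording.

    Defaults mirror the acquisition protocol the pipeline targets: 10 s at
    250 Hz, resting heart rate, mild RR jitter, modest white noise and
    baseline wander, patch z-attenuation kappa = 0.3, linear projection.
    """

    duration: float = 10.0
    fs: float = 250.0
    morphology: BeatMorphology = field(default_factory=default_morphology)
    kappa: float = 0.3
    pathologies: tuple = ()
    nonlinearity: float = 0.0
    noise_white_uv: float = 5.0
    wander_uv: float = 30.0
    wander_hz: float = 0.25
    rr_jitter: float = 0.03
    #: per-beat random rotation (deg, std) of the wave amplitude vectors,
    #: emulating respiratory modulation of the electrical axis
    axis_wobble_deg: float = 4.0
    seed: int = 0
    subject: str = ""

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0:
            raise SynthConfigError("fs and duration must be positive")
        self.pathologies = tuple(self.pathologies)


@dataclass
class PairedRecording:
    """A simultaneous (patch, 12-lead) pair with analytic ground truth."""

    patch: MultiLeadRecord
    target: MultiLeadRecord
    beats: list

    def __post_init__(self):
        if self.patch.fs != self.target.fs or \
                self.patch.n_samples != self.target.n_samples:
            raise ValueError("patch and target must share fs and length")

    @property
    def fs(self) -> float:
        return self.patch.fs

    @property
    def n_samples(self) -> int:
        return self.patch.n_samples


def _small_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    """Random rotation about a random axis, angle ~ N(0, sigma) clipped 3σ."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(float(np.clip(rng.normal(0.0, sigma_deg),
                                   -3 * sigma_deg, 3 * sigma_deg)))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def synth_paired_recording(config: SynthConfig) -> PairedRecording:
    """Generate one paired recording; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    rr_seq = _rr_sequence(config.morphology.heart_rate, config.duration,
                          config.rr_jitter, rng)
    n_beats = len(rr_seq)

    per_beat = [config.morphology] * n_beats
    labels = ["normal"] * n_beats
    for spec in config.pathologies:
        if spec.kind == "ectopic":
            affected = [i for i in spec.beat_indices if 0 <= i < n_beats]
        else:
            affected = range(n_beats)
        for i in affected:
            per_beat[i] = apply_pathology(per_beat[i], spec)
            if spec.kind != "none":
                labels[i] = spec.kind if labels[i] == "normal" \
                    else labels[i] + "+" + spec.kind

    if config.axis_wobble_deg > 0:
        wobbled = []
        for m in per_beat:
            rot = _small_rotation(rng, config.axis_wobble_deg)
            wobbled.append(replace(
                m, amps={w: rot @ m.amps[w] for w in WAVES}))
        per_beat = wobbled

    n = int(round(config.duration * config.fs))
    dipole = _synth_dipole(per_beat, rr_seq, config.fs, n)

    beats = []
    t0 = 0.0
    for morph, rr, label in zip(per_beat, rr_seq, labels):
        b = _beat_ground_truth(morph, t0, rr, label)
        if b.r_time < config.duration - EDGE_MARGIN_S:
            beats.append(b)
        t0 += rr

    patch = project_leads(dipole, patch_leadfield(config.kappa),
                          config.nonlinearity, config.fs, config.subject)
    target = project_leads(dipole, standard12_leadfield(),
                           config.nonlinearity, config.fs, config.subject)

    t = np.arange(n) / config.fs
    for rec in (patch, target):
        noise = np.zeros_like(rec.data)
        if config.noise_white_uv > 0:
            noise += rng.normal(0.0, config.noise_white_uv, size=rec.data.shape)
        if config.wander_uv > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=rec.n_leads)
            amp = config.wander_uv * rng.uniform(0.7, 1.3, size=rec.n_leads)
            noise += amp[None, :] * np.sin(
                2.0 * np.pi * config.wander_hz * t[:, None] + phase[None, :])
        rec.data = rec.data + noise

    return PairedRecording(patch=patch, target=target, beats=beats)


# --------------------------------------------------------------------------
# ground-truth sidecar

def ground_truth_to_dict(beats) -> dict:
    return {"beats": [
        {"r_time": b.r_time, "label": b.label,
         "fiducials": {k: (None if v is None else float(v))
                       for k, v in b.fiducials.items()}}
        for b in beats]}


def write_ground_truth(beats, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_to_dict(beats), fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> list:
    with open(path) as fh:
        d = json.load(fh)
    return [GroundTruthBeat(r_time=b["r_time"], fiducials=b["fiducials"],
                            label=b["label"]) for b in d["beats"]]
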