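"""Synthetic resting-state EEG with planted microstate structure.

Real clinical recordings from the population of interest cannot be shared,
so every downstream stage is validated against cohorts generated here with
known ground truth. A cohort consists of two groups — adults with Down
syndrome without (DS) and with (DS-AD) Alzheimer-type dementia — whose
microstate dynamics differ in planted, recoverable ways: DS-AD subjects
dwell longer in the class-A map and shorter in the class-D map.

The generative model, per subject:

1. a semi-Markov label sequence over K template maps, dwell times gamma
   distributed (shape 2) around the group/class mean duration, successor
   classes drawn proportionally to an occurrence bias with self-transitions
   excluded;
2. scalp potentials v(t) = a(t) * map_{s(t)} + noise, where a(t) is an
   alpha-band sinusoid with a slowly wandering amplitude envelope and the
   noise is spatially correlated Gaussian scaled to the requested SNR;
3. average-referencing sample by sample.

Defaults mirror the study population the package targets: 10 DS and 15
DS-AD subjects, 19-channel 10-20 montage at 1 kHz, per-class mean durations
taken from the published group means, 30-170 one-second epochs per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording, write_fif
from .montage import CHANNELS_1020, standard_1020_positions, validate_montage

#: Published group-mean microstate durations (ms), classes A-D.
DS_DURATIONS_MS = (65.94, 70.79, 91.61, 81.52)
DSAD_DURATIONS_MS = (73.19, 71.08, 89.77, 75.79)
#: Published group-mean occurrences (1/s), used as relative class biases.
DS_OCCURRENCE = (2.75, 2.74, 3.66, 3.37)
DSAD_OCCURRENCE = (3.03, 2.88, 3.59, 3.19)
#: DSQIID screening score: group mean, SD; scores live on [0, 53].
DS_DSQIID = (2.60, 2.84)
DSAD_DSQIID = (21.6, 5.72)
DS_AGE = (47.1, 9.49)
DSAD_AGE = (51.80, 5.13)
#: Per-subject 1-s epoch counts: group mean, SD, clipped to [30, 170].
DS_EPOCHS = (108.3, 57.72)
DSAD_EPOCHS = (86.80, 52.85)

GROUPS = ("DS", "DS-AD")
ARCHETYPES = ("A", "B", "C", "D", "E", "F")


@dataclass
class TemplateSet:
    """Planted template topographies on a spherical montage."""

    maps: np.ndarray                    # (K, C), unit-norm zero-mean rows
    montage: np.ndarray                 # (C, 3) unit sphere positions
    ch_names: list[str]
    archetype_labels: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.montage = validate_montage(self.montage)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("template rows must be unit-norm")

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    ``mean_durations_ms`` and ``occurrence_bias`` map group name to a
    per-class tuple; ``epochs_per_subject`` gives the truncation range for
    the group-conditional epoch-count draw.
    """

    n_subjects_per_group: dict = field(
        default_factory=lambda: {"DS": 10, "DS-AD": 15})
    n_states: int = 4
    mean_durations_ms: dict = field(
        default_factory=lambda: {"DS": DS_DURATIONS_MS,
                                 "DS-AD": DSAD_DURATIONS_MS})
    occurrence_bias: dict = field(
        default_factory=lambda: {"DS": DS_OCCURRENCE,
                                 "DS-AD": DSAD_OCCURRENCE})
    sampling_rate: float = 1000.0
    alpha_freq: float = 10.0
    snr: float = 4.0
    epoch_length_s: float = 1.0
    epochs_per_subject: tuple[int, int] = (30, 170)
    epoch_count_params: dict = field(
        default_factory=lambda: {"DS": DS_EPOCHS, "DS-AD": DSAD_EPOCHS})
    min_duration_ms: float = 10.0
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        if not 2 <= self.n_states <= 8:
            raise ValueError("n_states must be between 2 and 8")
        if self.sampling_rate <= 0 or self.alpha_freq <= 0:
            raise ValueError("rates must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.epochs_per_subject[0] < 30:
            raise ValueError("epochs_per_subject lower bound must be >= 30 "
                             "(the subject-inclusion rule)")
        for group in self.n_subjects_per_group:
            durs = np.asarray(self.mean_durations_ms[group][:self.n_states])
            if np.any(durs <= 0):
                raise ValueError(f"mean durations for {group} must be > 0")
            bias = np.asarray(self.occurrence_bias[group][:self.n_states])
            if np.any(bias < 0) or bias.sum() == 0:
                raise ValueError(f"occurrence bias for {group} must be "
                                 "non-negative and not all zero")
        return self


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    templates: TemplateSet
    labels: dict                         # subject_id -> (n_samples,) int
    features: pd.DataFrame               # per subject x class truth
    metadata: pd.DataFrame               # subject_id, group, age, gender, dsqiid


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _archetype_fields(pos: np.ndarray) -> np.ndarray:
    """Six smooth dipolar scalp fields in the classic archetype geometry.

    x: right, y: anterior, z: up. A and B are the two diagonal gradients,
    C the anterior-posterior axis, D a fronto-central peak against the
    periphery, E/F left-right and occipito-central variants used when more
    than four states are requested.
    """
    x, y, z = pos.T
    fields = np.stack([
        -x - 0.55 * y,     # A: left-posterior vs right-anterior diagonal
        x - 0.55 * y,      # B: right-posterior vs left-anterior diagonal
        y,                 # C: anterior vs posterior
        z + 0.3 * y,       # D: fronto-central peak vs periphery
        x,                 # E: left vs right
        z - 0.8 * y,       # F: centro-parietal variant
    ])
    return fields


def make_templates(n_states: int = 4,
                   montage: np.ndarray | None = None,
                   ch_names: list[str] | None = None,
                   seed: int = 0,
                   roughness: float = 0.05) -> TemplateSet:
    """Construct K planted microstate template maps.

    Maps are smooth dipolar fields over the montage matching the classical
    archetype geometries, with a small seeded perturbation (`roughness`,
    relative amplitude) so different seeds give distinct but recognisable
    topographies. Rows are zero-mean (average-reference consistent) and
    unit-norm.
    """
    if not 2 <= n_states <= 8:
        raise ValueError("n_states must be between 2 and 8")
    if montage is None:
        montage = standard_1020_positions()
        ch_names = list(CHANNELS_1020)
    montage = validate_montage(montage)
    if montage.shape[0] < 8:
        raise ValueError("montage must have at least 8 electrodes")
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(montage.shape[0])]

    rng = np.random.default_rng(seed)
    base = _archetype_fields(montage)
    if n_states > base.shape[0]:
        # extra states beyond the named archetypes: random smooth dipoles
        extra = rng.standard_normal((n_states - base.shape[0], 3)) @ montage.T
        base = np.concatenate([base, extra], axis=0)
    maps = base[:n_states].astype(float)

    # seeded smooth perturbation: a random linear field per map
    bump = (rng.standard_normal((n_states, 3)) @ montage.T)
    bump /= np.linalg.norm(bump, axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    maps = maps + roughness * bump

    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)

    labels = [ARCHETYPES[k] if k < len(ARCHETYPES) else f"M{k + 1}"
              for k in range(n_states)]
    return TemplateSet(maps=maps, montage=montage, ch_names=list(ch_names),
                       archetype_labels=labels)


# ---------------------------------------------------------------------------
# label dynamics
# ---------------------------------------------------------------------------

def simulate_labels(spec: SimulationSpec, group: str, n_samples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov microstate label sequence for one subject.

    Dwell times are gamma(shape 2) with the group/class mean duration,
    floored at ``spec.min_duration_ms``; the successor class is drawn
    proportionally to the occurrence bias with self-transitions excluded.
    """
    spec.validate()
    k = spec.n_states
    means = np.asarray(spec.mean_durations_ms[group][:k], dtype=float)
    bias = np.asarray(spec.occurrence_bias[group][:k], dtype=float)
    p = bias / bias.sum()

    labels = np.empty(n_samples, dtype=np.int64)
    t = 0
    current = int(rng.choice(k, p=p))
    while t < n_samples:
        dur_ms = max(spec.min_duration_ms,
                     rng.gamma(shape=2.0, scale=means[current] / 2.0))
        length = max(1, int(round(dur_ms * spec.sampling_rate / 1000.0)))
        labels[t:t + length] = current
        t += length
        if p[current] < 1.0:
            q = p.copy()
            q[current] = 0.0
            q /= q.sum()
            current = int(rng.choice(k, p=q))
    return labels


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _spatial_noise(n_channels: int, n_samples: int, montage: np.ndarray,
                   rng: np.random.Generator,
                   correlation_scale: float = 0.7) -> np.ndarray:
    """Gaussian noise with distance-dependent inter-channel correlation."""
    d = np.linalg.norm(montage[:, None, :] - montage[None, :, :], axis=-1)
    cov = np.exp(-(d / correlation_scale) ** 2)
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(n_channels))
    return chol @ rng.standard_normal((n_channels, n_samples))


def _slow_envelope(n_samples: int, fs: float, rng: np.random.Generator,
                   cutoff_hz: float = 1.0, depth: float = 0.5) -> np.ndarray:
    """Positive, slowly wandering amplitude envelope with mean ~1."""
    from scipy import signal as sp_signal

    white = rng.standard_normal(n_samples + int(fs))
    sos = sp_signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    slow = sp_signal.sosfiltfilt(sos, white)[int(fs) // 2:][:n_samples]
    slow = slow / (np.std(slow) + 1e-12)
    return np.clip(1.0 + depth * slow, 0.2, None)


def align_labels_to_carrier(labels: np.ndarray,
                            crossings: np.ndarray) -> np.ndarray:
    """Snap state-switch times to the nearest carrier zero-crossing.

    Scalp topography in the microstate model stays stable across whole
    field-power lobes and flips at field-power minima; snapping each
    segment boundary to the nearest zero-crossing of the alpha carrier
    renders exactly that (and keeps the synthesized signal continuous,
    since the map switch happens where the carrier amplitude is zero).
    Segments squeezed below one inter-crossing gap vanish.
    """
    labels = np.asarray(labels)
    if len(crossings) == 0:
        return labels.copy()
    change = np.flatnonzero(np.diff(labels)) + 1
    snapped = crossings[np.searchsorted(crossings, change).clip(
        1, len(crossings) - 1)]
    prev = crossings[np.searchsorted(crossings, change).clip(
        1, len(crossings) - 1) - 1]
    use_prev = (change - prev) < (snapped - change)
    snapped = np.where(use_prev, prev, snapped)

    out = np.empty_like(labels)
    starts = np.concatenate(([0], snapped))
    # drop collapsed segments: keep the label of the last boundary winner
    seg_labels = labels[np.concatenate(([0], change))]
    for lab, s, e in zip(seg_labels, starts,
                         np.concatenate((starts[1:], [len(labels)]))):
        if e > s:
            out[s:e] = lab
    return out


def synthesize_eeg(templates: TemplateSet, labels: np.ndarray,
                   spec: SimulationSpec, rng: np.random.Generator,
                   subject_id: str = "", align_switches: bool = True
                   ) -> tuple[Recording, np.ndarray]:
    """Render a label sequence into a multichannel recording.

    v(t) = a(t) * map_{s(t)} + noise, with a(t) an alpha sinusoid under a
    slow random envelope, noise spatially correlated Gaussian scaled so the
    RMS amplitude ratio of signal to noise equals ``spec.snr``; the result
    is average-referenced sample by sample. Amplitudes are scaled to a
    realistic ~20 µV RMS scalp signal.

    With ``align_switches`` (the default) segment boundaries are snapped
    to the carrier's zero-crossings before rendering — see
    :func:`align_labels_to_carrier`. Returns ``(recording,
    realized_labels)``; the realized labels are the ground truth for the
    rendered signal.
    """
    labels = np.asarray(labels)
    k, n_ch = templates.maps.shape
    if labels.max(initial=0) >= k:
        raise ValueError("label index exceeds template count")
    n = len(labels)
    fs = spec.sampling_rate

    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * spec.alpha_freq * t + phase)
    if align_switches:
        crossings = np.flatnonzero(np.diff(np.signbit(carrier))) + 1
        labels = align_labels_to_carrier(labels, crossings)
    envelope = _slow_envelope(n, fs, rng)
    amplitude = 20.0 * np.sqrt(n_ch)       # ~20 µV GFP at envelope 1
    a = amplitude * envelope * carrier

    signal = templates.maps[labels].T * a[None, :]
    signal_rms = np.sqrt(np.mean(signal ** 2))
    if np.isfinite(spec.snr):
        noise = _spatial_noise(n_ch, n, templates.montage, rng)
        noise *= signal_rms / (spec.snr * np.sqrt(np.mean(noise ** 2)))
    else:
        noise = 0.0
    data = signal + noise
    data -= data.mean(axis=0, keepdims=True)
    rec = Recording(data=data, fs=fs, ch_names=list(templates.ch_names),
                    montage=templates.montage, reference="average",
                    annotations={"eyes_closed": 0.0}, subject_id=subject_id)
    return rec, labels


# ---------------------------------------------------------------------------
# ground-truth features
# ---------------------------------------------------------------------------

def true_features(labels: np.ndarray, fs: float, n_states: int,
                  subject_id: str = "") -> pd.DataFrame:
    """Duration / occurrence / coverage of a ground-truth label sequence."""
    from .stats import label_features  # late import to avoid a cycle

    return label_features(labels, fs, n_states, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal draw by rejection (bounds are generous)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(spec: SimulationSpec | None = None,
                    out_dir: str | Path | None = None,
                    templates: TemplateSet | None = None
                    ) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """Generate a full two-group cohort with ground truth.

    Returns ``(recordings, metadata, ground_truth)``. When `out_dir` is
    given, writes one FIF file per subject, a ``metadata.csv`` and
    compressed ground-truth label files.
    """
    spec = (spec or SimulationSpec()).validate()
    master = np.random.default_rng(spec.seed)
    if templates is None:
        templates = make_templates(spec.n_states, seed=spec.seed)

    recordings: list[Recording] = []
    meta_rows, feat_frames, labels_map = [], [], {}
    sid_counter = 0
    for group in GROUPS:
        n_subj = spec.n_subjects_per_group.get(group, 0)
        if n_subj == 0:
            continue
        em, es = spec.epoch_count_params[group]
        am, asd = DS_AGE if group == "DS" else DSAD_AGE
        dm, dsd = DS_DSQIID if group == "DS" else DSAD_DSQIID
        lo, hi = spec.epochs_per_subject
        epoch_counts = np.round(
            _truncnorm(master, em, es, lo, hi, n_subj)).astype(int)
        ages = np.round(_truncnorm(master, am, asd, 30, 75, n_subj), 1)
        dsqiid = np.round(_truncnorm(master, dm, dsd, 0, 53, n_subj), 1)
        genders = master.integers(0, 2, size=n_subj)

        for i in range(n_subj):
            sid_counter += 1
            sid = f"sub-{sid_counter:02d}"
            # independent per-subject substream so cohort-size changes do
            # not perturb other subjects' draws
            sub_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, sid_counter]))
            n_samples = int(epoch_counts[i] * spec.epoch_length_s
                            * spec.sampling_rate)
            labels = simulate_labels(spec, group, n_samples, sub_rng)
            rec, labels = synthesize_eeg(templates, labels, spec, sub_rng,
                                         subject_id=sid)
            recordings.append(rec)
            labels_map[sid] = labels
            feat_frames.append(
                true_features(labels, spec.sampling_rate, spec.n_states,
                              subject_id=sid))
            meta_rows.append({
                "subject_id": sid, "group": group, "age": float(ages[i]),
                "gender": int(genders[i]), "dsqiid": float(dsqiid[i]),
            })

    metadata = pd.DataFrame(
        meta_rows, columns=["subject_id", "group", "age", "gender", "dsqiid"])
    features = (pd.concat(feat_frames, ignore_index=True)
                if feat_frames else pd.DataFrame())
    truth = GroundTruth(templates=templates, labels=labels_map,
                        features=features, metadata=metadata)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_fif(rec, out_dir / f"{rec.subject_id}_raw.fif")
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        for sid, lab in labels_map.items():
            pd.DataFrame({sid: lab}).to_csv(
                out_dir / f"{sid}_truth_labels.csv.gz", index=False)
        np.savetxt(out_dir / "true_templates.csv", templates.maps,
                   delimiter=",", header=",".join(templates.ch_names),
                   comments="")
    return recordings, metadata, truth


def shifted_spec(base: SimulationSpec | None = None, **overrides
                 ) -> SimulationSpec:
    """Convenience copy-with-overrides for cohort specs."""
    return replace(base or SimulationSpec(), **overrides).validate()
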