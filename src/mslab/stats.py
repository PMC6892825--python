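"""Per-subject microstate features and transition-syntax statistics.

Features per subject and class: mean duration (ms), occurrence (appearances
per second) and coverage (fraction of samples). These satisfy the exact
identity duration * occurrence / 1000 = coverage when computed from one
label sequence, which downstream tests exploit.

Syntax analysis compares each subject's observed transition probabilities
(between consecutive distinct microstates) with the probabilities expected
from class occurrence alone (independence null excluding self-transitions),
using the chi-square distance and a subject-level permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelSequence


# ---------------------------------------------------------------------------
# run-length encoding and features
# ---------------------------------------------------------------------------

def run_length_encode(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of a label sequence as ``(label, start, length)``."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot encode an empty sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(labels[s]), int(s), int(e - s))
            for s, e in zip(starts, ends)]


def run_length_decode(runs: list[tuple[int, int, int]]) -> np.ndarray:
    """Inverse of :func:`run_length_encode`."""
    total = sum(length for _, _, length in runs)
    out = np.empty(total, dtype=np.int64)
    for label, start, length in runs:
        out[start:start + length] = label
    return out


def label_features(labels: np.ndarray, fs: float, n_states: int,
                   subject_id: str = "", gev: float = np.nan
                   ) -> pd.DataFrame:
    """Duration / occurrence / coverage per class for one label sequence.

    Classes absent from the sequence get duration 0 with ``present=False``.
    Returns a tidy frame with one row per class.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    runs = run_length_encode(labels)
    total_s = len(labels) / fs
    rows = []
    for k in range(n_states):
        lens = [length for lab, _, length in runs if lab == k]
        n_runs = len(lens)
        coverage = sum(lens) / len(labels)
        duration_ms = (np.mean(lens) * 1000.0 / fs) if n_runs else 0.0
        occurrence = n_runs / total_s
        rows.append({
            "subject_id": subject_id, "class": k,
            "duration_ms": float(duration_ms),
            "occurrence_hz": float(occurrence),
            "coverage": float(coverage),
            "present": bool(n_runs), "gev": float(gev),
        })
    return pd.DataFrame(rows)


def sequence_features(ls: LabelSequence, gev: float = np.nan) -> pd.DataFrame:
    """Features of a back-fitted :class:`LabelSequence`."""
    return label_features(ls.labels, ls.fs, ls.n_states,
                          subject_id=ls.subject_id, gev=gev)


# ---------------------------------------------------------------------------
# transition tables
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """Observed vs expected off-diagonal transition probabilities."""

    observed: np.ndarray
    expected: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("observed", "expected"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(np.diag(m), 0.0):
                raise ValueError(f"{name} must have a zero diagonal")
            setattr(self, name, m)


def observed_transitions(labels: np.ndarray, n_states: int) -> np.ndarray:
    """Empirical transition probabilities between consecutive distinct runs.

    Counts each change of microstate class and normalises by the total
    number of transitions; the diagonal is structurally zero.
    """
    runs = run_length_encode(labels)
    seq = [lab for lab, _, _ in runs]
    if len(seq) < 2:
        raise ValueError("need at least two runs to count transitions")
    counts = np.zeros((n_states, n_states))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a, b] += 1
    return counts / counts.sum()


def expected_transitions(occurrence: np.ndarray) -> np.ndarray:
    """Transition probabilities expected from occurrence alone.

    Under independence with self-transitions excluded,
    ``E_ij = p_i p_j / sum_{k != l} p_k p_l`` with p the occurrence
    distribution normalised to sum 1.
    """
    p = np.asarray(occurrence, dtype=float)
    if np.any(p < 0) or p.sum() == 0:
        raise ValueError("occurrence must be non-negative and not all zero")
    p = p / p.sum()
    e = np.outer(p, p)
    np.fill_diagonal(e, 0.0)
    return e / e.sum()


def transition_table(labels: np.ndarray, fs: float, n_states: int,
                     subject_id: str = "") -> TransitionTable:
    """Observed and expected transition tables for one subject."""
    feats = label_features(labels, fs, n_states)
    obs = observed_transitions(labels, n_states)
    exp = expected_transitions(feats["occurrence_hz"].to_numpy())
    return TransitionTable(observed=obs, expected=exp, subject_id=subject_id)


def chi_square_distance(obs: np.ndarray, exp: np.ndarray) -> float:
    """Chi-square distance over off-diagonal cells.

    ``sum_{i != j} (obs_ij - exp_ij)^2 / exp_ij``; cells where both are
    zero contribute nothing, a zero expectation under a positive
    observation is undefined.
    """
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("matrices must share a shape")
    if obs.ndim == 2 and obs.shape[0] == obs.shape[1]:
        off = ~np.eye(obs.shape[0], dtype=bool)
    else:  # already a flat vector of off-diagonal cells
        off = np.ones(obs.shape, dtype=bool)
    o, e = obs[off], exp[off]
    if np.any((e == 0) & (o > 0)):
        raise ValueError("chi-square distance undefined: zero expectation "
                         "under positive observation")
    mask = e > 0
    return float(np.sum((o[mask] - e[mask]) ** 2 / e[mask]))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def syntax_permutation_test(tables: list[TransitionTable],
                            n_perm: int = 5000,
                            seed: int | np.random.Generator = 0
                            ) -> dict:
    """Permutation test of observed vs expected transition structure.

    The statistic is the chi-square distance between the across-subject
    mean observed and mean expected matrices. Under the null the two
    matrices within each subject are exchangeable, so each permutation
    swaps a random subset of subjects' observed/expected pairs. The
    p-value uses the add-one estimator ``(1 + #{T_perm >= T}) / (1 +
    n_perm)``.
    """
    if len(tables) < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    obs = np.stack([t.observed for t in tables])   # (n, K, K)
    exp = np.stack([t.expected for t in tables])
    n = len(tables)
    t_obs = chi_square_distance(obs.mean(axis=0), exp.mean(axis=0))

    t_perm = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(n) < 0.5
        o = np.where(swap[:, None, None], exp, obs).mean(axis=0)
        e = np.where(swap[:, None, None], obs, exp).mean(axis=0)
        t_perm[i] = chi_square_distance(o, e)
    p = (1.0 + np.sum(t_perm >= t_obs)) / (1.0 + n_perm)
    return {"statistic": t_obs, "p_value": float(p), "n_perm": n_perm,
            "null": t_perm}


def features_table(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-subject feature frames into one tidy table."""
    return pd.concat(frames, ignore_index=True)


def tables_to_frame(tables: list[TransitionTable]) -> pd.DataFrame:
    """Long-format observed/expected transition probabilities."""
    rows = []
    for t in tables:
        k = t.observed.shape[0]
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append({"subject_id": t.subject_id, "from": i, "to": j,
                             "observed": t.observed[i, j],
                             "expected": t.expected[i, j]})
    return pd.DataFrame(rows)
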