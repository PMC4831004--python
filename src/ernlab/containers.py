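"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical column order of a trial table (TSV header).
TRIAL_COLUMNS = [
    "subject_id", "sex", "age", "trial_index", "congruency", "distance",
    "rsi", "next_rsi", "response_hand", "accuracy", "rt", "multi_response",
]


@dataclass
class EpochSet:
    """Response-locked single-trial EEG tensor for one subject.

    data: (n_trials, n_electrodes, n_timepoints) in uV; times in ms with 0 at
    response onset; trial_link holds 0-based row positions into the subject's
    trial table.
    """

    data: np.ndarray
    times: np.ndarray
    electrode_labels: list
    subject_id: str
    trial_link: np.ndarray
    sampling_rate: float = 500.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_link = np.asarray(self.trial_link, dtype=int)
        n, e, t = self.data.shape
        if len(self.times) != t:
            raise ValueError("times length inconsistent with data")
        if len(self.electrode_labels) != e:
            raise ValueError("electrode_labels inconsistent with data")
        if len(self.trial_link) != n:
            raise ValueError("trial_link inconsistent with data")
        if len(np.unique(self.trial_link)) != n:
            raise ValueError("trial_link must be injective")

    @property
    def n_trials(self):
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, self.electrode_labels,
                        self.subject_id, self.trial_link[mask],
                        self.sampling_rate)

    def copy_with(self, data) -> "EpochSet":
        return EpochSet(data, self.times, self.electrode_labels,
                        self.subject_id, self.trial_link, self.sampling_rate)


@dataclass
class FirstLevelMap:
    """Per-subject SE-scaled regression weights (regressor x electrode x time)."""

    weights: np.ndarray
    regressor_names: list
    times: np.ndarray
    electrode_labels: list
    subject_id: str
    n_trials: int = 0
    n_nonconverged: int = 0

    def get(self, regressor: str) -> np.ndarray:
        return self.weights[self.regressor_names.index(regressor)]


@dataclass
class CouplingMap:
    """Standardized EEG->next-RT coupling coefficients (electrode x time)."""

    coef: np.ndarray
    times: np.ndarray
    electrode_labels: list
    subject_id: str
    n_error_trials: int = 0


@dataclass
class GroupResult:
    """Second-level maps: per predictor coefficient / t / p (electrode x time)."""

    coef: np.ndarray  # (n_predictors, n_electrodes, n_timepoints)
    t: np.ndarray
    p: np.ndarray
    predictor_names: list
    times: np.ndarray
    electrode_labels: list
    df_resid: int
    n_subjects: int

    def get(self, predictor: str, which: str = "t") -> np.ndarray:
        i = self.predictor_names.index(predictor)
        return getattr(self, which)[i]


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome."""

    accuracy: float
    fold_accuracies: np.ndarray
    n_per_class: int
    permutation_p: float | None = None
    n_permutations: int = 0
    permutation_cv_splits: int | None = None
    searchlight: dict = field(default_factory=dict)  # label -> mean accuracy
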