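"""Text-format I/O for pulse recordings, cohort manifests and result tables.

All on-disk formats are plain CSV so that fixtures and results stay
human-inspectable:

* pulse sample file — one float per row, optional single header line;
* cohort manifest   — columns ``record_path, subject_id, sex, hand``;
* scale profile     — columns ``tau, measure, value`` (``NA`` = undefined);
* summary table     — columns ``tau, male_mean, male_sd, female_mean,
  female_sd, p_value`` (one row per time scale, means/SDs to 4 decimals).

The sampling rate is carried in the manifest / call site, not in the sample
file, so sample files stay minimal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Hand",
    "Measure",
    "PulseRecord",
    "ManifestEntry",
    "CohortManifest",
    "ScaleProfile",
    "GroupScaleSummary",
    "PulseParseError",
    "read_pulse_csv",
    "write_pulse_csv",
    "read_manifest",
    "write_manifest",
    "read_scale_profiles",
    "write_scale_profiles",
    "write_summary_table",
]

#: token used on disk for an undefined entropy value (e.g. zero sample-entropy
#: matches); in memory undefined values are ``nan``.
NA_TOKEN = "NA"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Hand(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class Measure(str, enum.Enum):
    """The four refined composite multiscale entropy measures."""

    RC_MSE = "rc_mse"  # sample entropy
    RC_MFE = "rc_mfe"  # fuzzy entropy
    RC_MPE = "rc_mpe"  # permutation entropy
    RC_MDE = "rc_mde"  # dispersion entropy


class PulseParseError(ValueError):
    """Raised when a pulse sample file cannot be parsed."""


@dataclass(frozen=True)
class PulseRecord:
    """A single-channel pressure-pulse time series with subject metadata.

    Parameters
    ----------
    samples
        Pulse amplitudes in arbitrary pressure units, file order preserved.
    fs
        Sampling rate in Hz (the study hardware samples at 200 Hz).
    subject_id, sex, hand
        Cohort metadata; defaults mark the record as unattributed.
    """

    samples: np.ndarray
    fs: float = 200.0
    subject_id: str = ""
    sex: Sex = Sex.UNKNOWN
    hand: Hand = Hand.UNKNOWN

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def with_samples(self, samples: np.ndarray) -> "PulseRecord":
        """Copy of this record with the samples replaced, metadata kept."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class ManifestEntry:
    record_path: str
    subject_id: str
    sex: Sex
    hand: Hand


@dataclass
class CohortManifest:
    """Maps record files to subject sex and hand for a two-group study."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.hand) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (subject_id, hand) pair in manifest")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class ScaleProfile:
    """Entropy value per time scale for one record and one measure.

    ``values`` maps the scale factor tau (consecutive integers from 1) to the
    entropy estimate; an undefined estimate (possible for crisp sample-entropy
    counting when no template pairs match) is stored as ``nan``.
    """

    subject_id: str
    hand: Hand
    measure: Measure
    values: dict[int, float]

    def __post_init__(self) -> None:
        taus = sorted(self.values)
        if taus != list(range(1, len(taus) + 1)):
            raise ValueError("scales must be consecutive integers starting at 1")
        self.values = {t: float(self.values[t]) for t in taus}

    @property
    def tau_max(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        """Values ordered by scale, ``nan`` marking undefined entries."""
        return np.array([self.values[t] for t in sorted(self.values)])


@dataclass(frozen=True)
class GroupScaleSummary:
    """One row of a per-scale male/female comparison table."""

    tau: int
    measure: Measure
    hand: Hand
    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float
    p_value: float
    test_used: str = "t_test"

    def __post_init__(self) -> None:
        if self.male_sd < 0 or self.female_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# pulse sample files
# ---------------------------------------------------------------------------

def read_pulse_csv(
    path: str | Path,
    fs: float = 200.0,
    subject_id: str = "",
    sex: Sex | str = Sex.UNKNOWN,
    hand: Hand | str = Hand.UNKNOWN,
) -> PulseRecord:
    """Read a one-column pulse sample file.

    The file holds one numeric amplitude per line; a single non-numeric first
    line is treated as a header.  A non-numeric value anywhere else raises
    :class:`PulseParseError` naming the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    values: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip().rstrip(",")
        if not text:
            continue
        try:
            values.append(float(text))
        except ValueError:
            if lineno == 1 and not values:
                continue  # header line
            raise PulseParseError(
                f"{path}: non-numeric value {text!r} at line {lineno}"
            ) from None
    if not values:
        raise PulseParseError(f"{path}: no numeric samples found")
    return PulseRecord(
        samples=np.array(values),
        fs=fs,
        subject_id=subject_id,
        sex=Sex(sex),
        hand=Hand(hand),
    )


def write_pulse_csv(record: PulseRecord, path: str | Path) -> None:
    """Write samples one per line with 17 significant digits (lossless round-trip)."""
    Path(path).write_text(
        "\n".join(format(v, ".17g") for v in record.samples) + "\n"
    )


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, dtype=str)
    required = ["record_path", "subject_id", "sex", "hand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    entries = [
        ManifestEntry(
            record_path=row.record_path,
            subject_id=row.subject_id,
            sex=Sex(row.sex),
            hand=Hand(row.hand),
        )
        for row in df.itertuples()
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        {
            "record_path": [e.record_path for e in manifest],
            "subject_id": [e.subject_id for e in manifest],
            "sex": [e.sex.value for e in manifest],
            "hand": [e.hand.value for e in manifest],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scale profiles
# ---------------------------------------------------------------------------

def write_scale_profiles(profiles: Iterable[ScaleProfile], path: str | Path) -> None:
    """Write per-record entropy profiles as long-format CSV.

    Columns: subject_id, hand, measure, tau, value.  Undefined entropies are
    rendered as the literal token ``NA``.
    """
    rows = []
    for p in profiles:
        for tau, v in p.values.items():
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "hand": p.hand.value,
                    "measure": p.measure.value,
                    "tau": tau,
                    "value": NA_TOKEN if math.isnan(v) else format(v, ".17g"),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scale_profiles(path: str | Path) -> list[ScaleProfile]:
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    profiles = []
    for (sid, hand, measure), grp in df.groupby(
        ["subject_id", "hand", "measure"], sort=False
    ):
        values = {
            int(t): (math.nan if v == NA_TOKEN else float(v))
            for t, v in zip(grp["tau"], grp["value"])
        }
        profiles.append(
            ScaleProfile(
                subject_id=str(sid),
                hand=Hand(hand),
                measure=Measure(measure),
                values=values,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# group summary tables
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return NA_TOKEN if math.isnan(v) else format(v, ".4f")


def write_summary_table(
    rows: Sequence[GroupScaleSummary],
    path: str | Path,
    extra_columns: Mapping[str, Sequence[float]] | None = None,
) -> None:
    """Write a per-scale male/female comparison table as CSV.

    One row per time scale; means, SDs and p-values are rendered to 4
    decimals, mirroring the presentation of the study tables.  ``extra_columns``
    lets the caller append clearly separated auxiliary columns (e.g. a
    Holm-corrected p-value) after the canonical six.
    """
    taus = [r.tau for r in rows]
    if len(taus) != len(set(taus)):
        raise ValueError(f"duplicate scale values in summary rows: {sorted(taus)}")
    data = {
        "tau": taus,
        "male_mean": [_fmt(r.male_mean) for r in rows],
        "male_sd": [_fmt(r.male_sd) for r in rows],
        "female_mean": [_fmt(r.female_mean) for r in rows],
        "female_sd": [_fmt(r.female_sd) for r in rows],
        "p_value": [_fmt(r.p_value) for r in rows],
    }
    if extra_columns:
        for name, vals in extra_columns.items():
            if len(vals) != len(rows):
                raise ValueError(f"extra column {name!r} length mismatch")
            data[name] = [_fmt(float(v)) for v in vals]
    pd.DataFrame(data).to_csv(path, index=False)
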