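"""Recording container and subject metadata.

A :class:`Recording` holds a multi-channel DC-coupled ECoG trace in
millivolts with a sampling rate in Hz.  Channels are identified by
electrode *roles*: the two ipsilateral electrodes over left primary motor
(M1) and primary sensory (S1) cortex, 2 mm apart, and the contralateral
right M1 electrode.  Time 0 is the start of the one-hour recording
(KCl application at the occipital craniotomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np

#: Canonical channel roles, in recording order.
ROLES = ("M1_left", "S1_left", "M1_right")

#: Distance between the two ipsilateral electrodes (M1 left / S1 left), mm.
ELECTRODE_DISTANCE_MM = 2.0

GENOTYPES = ("WT", "G301R")
GROUPS = ("male", "female", "aged_male", "PM_female")

_ROLE_ALIASES = {
    "M1_left": {"M1LEFT", "M1L", "LEFTM1", "M1LH"},
    "S1_left": {"S1LEFT", "S1L", "LEFTS1", "S1LH"},
    "M1_right": {"M1RIGHT", "M1R", "RIGHTM1", "M1RH"},
}


def resolve_role(label: str) -> str:
    """Map a channel label (e.g. ``"M1L"``, ``"m1 left"``) to its role.

    Raises
    ------
    RoleMappingError
        If the label matches none of the known electrode roles.
    """
    from .exceptions import RoleMappingError

    key = re.sub(r"[^A-Z0-9]", "", label.upper())
    for role, aliases in _ROLE_ALIASES.items():
        if key in aliases or key == re.sub(r"[^A-Z0-9]", "", role.upper()):
            return role
    raise RoleMappingError(f"cannot resolve channel label {label!r} to a role "
                           f"(known roles: {ROLES})")


@dataclass(frozen=True)
class SubjectMeta:
    """Genotype and group of one animal."""

    subject_id: str
    genotype: str = "WT"
    group: str = "male"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    def to_dict(self) -> dict:
        return {"subject_id": self.subject_id, "genotype": self.genotype,
                "group": self.group}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectMeta":
        return cls(subject_id=str(d["subject_id"]), genotype=d["genotype"],
                   group=d["group"])


@dataclass(frozen=True)
class FilterSpec:
    """Offline zero-phase band specification (high-pass and/or low-pass)."""

    highpass_hz: float | None = None
    lowpass_hz: float | None = None
    order: int = 2

    def __post_init__(self) -> None:
        if self.highpass_hz is not None and self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be > 0")
        if self.lowpass_hz is not None and self.lowpass_hz <= 0:
            raise ValueError("lowpass_hz must be > 0")
        if (self.highpass_hz is not None and self.lowpass_hz is not None
                and not self.highpass_hz < self.lowpass_hz):
            raise ValueError("need highpass_hz < lowpass_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, fs: float) -> None:
        from .exceptions import FilterError

        nyq = fs / 2.0
        for cut in (self.highpass_hz, self.lowpass_hz):
            if cut is not None and not (0 < cut < nyq):
                raise FilterError(f"cutoff {cut} Hz outside (0, {nyq}) for fs={fs}")


#: Offline chain for CSD (DC shift) analysis.
CSD_FILTER = FilterSpec(highpass_hz=0.005, lowpass_hz=100.0)
#: Offline chain for epileptiform-activity analysis.
EPI_FILTER = FilterSpec(highpass_hz=0.5, lowpass_hz=100.0)


@dataclass
class Recording:
    """Multi-channel ECoG trace.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in mV.
    fs
        Sampling rate, Hz.
    channels
        Ordered channel roles (see :data:`ROLES`).
    t0
        Time of the first sample, seconds (0 = start of KCl application).
    subject
        Optional subject metadata.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = ROLES
    t0: float = 0.0
    subject: SubjectMeta | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("number of channel labels must match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, role: str) -> np.ndarray:
        """Return the 1-D trace for one role."""
        try:
            i = self.channels.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}")
        return self.data[i]

    def copy_with(self, **kw) -> "Recording":
        d = dict(data=self.data, fs=self.fs, channels=self.channels,
                 t0=self.t0, subject=self.subject, flags=dict(self.flags))
        d.update(kw)
        return Recording(**d)
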