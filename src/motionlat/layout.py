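"""Channel layout: named electrode roles used throughout the analysis.

The analysis only needs a handful of named electrode roles: a midline
occipital set for the early visual components (P1/N1), left- and
right-hemisphere parieto-occipital sets for the motion-sensitive N2,
the two mastoids used as the offline reference, and the ocular channels
used for artifact screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ChannelLayout:
    """Electrode-role assignment.

    Parameters
    ----------
    occipital_set : list of str
        Midline occipital sites averaged for the P1 (motion) and N1
        (color-change) components.
    lh_set, rh_set : list of str
        Left / right parieto-occipital sites averaged for the N2.
        Must be disjoint and of equal size.
    mastoids : list of str
        The two reference channels (averaged offline reference).
    veog : list of str
        Vertical EOG channel(s), screened for blinks via peak-to-peak.
    heog : str
        Horizontal EOG channel, screened for lateral eye movements.
    """

    occipital_set: list[str] = field(
        default_factory=lambda: ["O1", "I1", "IZ", "I2", "O2"])
    lh_set: list[str] = field(default_factory=lambda: ["P5", "PO3", "PO7"])
    rh_set: list[str] = field(default_factory=lambda: ["P4", "PO4", "PO8"])
    mastoids: list[str] = field(default_factory=lambda: ["M1", "M2"])
    veog: list[str] = field(default_factory=lambda: ["VEOG"])
    heog: str = "HEOG"

    def __post_init__(self) -> None:
        eog = set(self.veog) | {self.heog}
        for name, chans in (("occipital_set", self.occipital_set),
                            ("lh_set", self.lh_set),
                            ("rh_set", self.rh_set),
                            ("mastoids", self.mastoids)):
            if eog & set(chans):
                raise ValueError(f"{name} overlaps EOG channels")
        if set(self.lh_set) & set(self.rh_set):
            raise ValueError("lh_set and rh_set overlap")
        if len(self.lh_set) != len(self.rh_set):
            raise ValueError("lh_set and rh_set must be equal-sized")

    @property
    def eog_channels(self) -> list[str]:
        return list(self.veog) + [self.heog]

    @property
    def scalp_channels(self) -> list[str]:
        """All non-EOG channels (order: occipital, LH, RH, mastoids)."""
        return (list(self.occipital_set) + list(self.lh_set)
                + list(self.rh_set) + list(self.mastoids))

    @property
    def analysis_channels(self) -> list[str]:
        """Channels screened by the absolute-amplitude artifact criterion."""
        return self.scalp_channels

    @property
    def channels(self) -> list[str]:
        return self.scalp_channels + self.eog_channels

    def to_dict(self) -> dict:
        return {
            "occipital_set": list(self.occipital_set),
            "lh_set": list(self.lh_set),
            "rh_set": list(self.rh_set),
            "mastoids": list(self.mastoids),
            "veog": list(self.veog),
            "heog": self.heog,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(**d)
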