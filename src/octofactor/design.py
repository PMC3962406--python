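"""The 2x2x2 factorial channel layout of the 8-plex experiment.

Eight reporter channels label the eight (knockout x ethanol x gender) condition
combinations; the dextrose-fed wild-type male channel (114) is the common
reference, so the seven informative "observations" are ratios of each remaining
channel over 114. The mapping below is the default; callers working with a
different labelling scheme can supply their own via YAML (see
:func:`load_channel_map`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "Condition",
    "CHANNEL_CONDITIONS",
    "REFERENCE_CHANNEL",
    "DEFAULT_OBSERVATIONS",
    "OBSERVATION_LABELS",
    "condition_of_channel",
    "load_channel_map",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the knockout x ethanol x gender factorial."""

    knockout: bool
    ethanol: bool
    female: bool

    @property
    def label(self) -> str:
        parts = []
        if self.female:
            parts.append("F")
        if self.knockout:
            parts.append("KO")
        if self.ethanol:
            parts.append("E")
        return "+".join(parts) if parts else "WT"


#: Reporter tag -> biological condition (default labelling scheme).
CHANNEL_CONDITIONS: dict[str, Condition] = {
    "113": Condition(knockout=False, ethanol=False, female=True),
    "114": Condition(knockout=False, ethanol=False, female=False),
    "115": Condition(knockout=False, ethanol=True, female=True),
    "116": Condition(knockout=False, ethanol=True, female=False),
    "117": Condition(knockout=True, ethanol=False, female=True),
    "118": Condition(knockout=True, ethanol=False, female=False),
    "119": Condition(knockout=True, ethanol=True, female=True),
    "121": Condition(knockout=True, ethanol=True, female=False),
}

REFERENCE_CHANNEL = "114"

#: The seven observations against the reference channel, in factorial order.
DEFAULT_OBSERVATIONS: list[str] = [
    f"{tag}:{REFERENCE_CHANNEL}"
    for tag in ("118", "116", "121", "113", "117", "115", "119")
]

#: Short condition labels for the seven default observations.
OBSERVATION_LABELS: dict[str, str] = {
    "118:114": "KO",
    "116:114": "E",
    "121:114": "KO+E",
    "113:114": "F",
    "117:114": "F+KO",
    "115:114": "F+E",
    "119:114": "F+KO+E",
}


def condition_of_channel(tag: str, channel_map: dict[str, Condition] | None = None) -> Condition:
    mapping = channel_map or CHANNEL_CONDITIONS
    try:
        return mapping[tag]
    except KeyError:
        raise KeyError(f"unknown reporter channel {tag!r}") from None


def load_channel_map(path: str | Path) -> dict[str, Condition]:
    """Load a channel->condition map from YAML.

    Expected layout::

        "113": {knockout: false, ethanol: false, female: true}
        ...
    """
    import yaml

    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return {
        str(tag): Condition(
            knockout=bool(spec["knockout"]),
            ethanol=bool(spec["ethanol"]),
            female=bool(spec["female"]),
        )
        for tag, spec in raw.items()
    }
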