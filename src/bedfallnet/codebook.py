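"""The contributing-factor codebook: single-letter codes A-V mapped to labels.

Twenty-two contributing factors to inpatient bed falls, each assigned a unique
alphabetical code. The default codebook shipped with the package carries the
standard labels (patient status, ward environment and equipment, medication,
caregiver, and nursing-practice factors).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator


@dataclass(frozen=True)
class Codebook:
    """Ordered map from single-letter factor code to its free-text label.

    Invariants: exactly 22 unique codes, the consecutive letters A-V, each with
    a non-empty label.
    """

    entries: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.entries)
        expected = list(string.ascii_uppercase[:22])
        if codes != expected:
            raise ValueError(
                f"codebook must contain exactly the 22 codes A-V in order; got {codes}"
            )
        for code, label in self.entries.items():
            if not isinstance(label, str) or not label.strip():
                raise ValueError(f"label for code {code!r} is empty")

    @property
    def codes(self) -> list[str]:
        return list(self.entries)

    def label(self, code: str) -> str:
        return self.entries[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: object) -> bool:
        return code in self.entries

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))


def default_codebook() -> Codebook:
    """The packaged 22-factor bed-fall codebook (codes A-V)."""
    text = resources.files("bedfallnet._resources").joinpath("codebook.json").read_text("utf-8")
    return Codebook(json.loads(text))
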