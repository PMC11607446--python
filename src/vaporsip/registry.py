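"""Canonical assignment of fatty-acid biomarkers to microbial groups.

The registry is shipped as data (``data/marker_registry.csv``) so users can
extend it; the file in the package is the frozen baseline:

* fungi: 18:1w9c, 18:2w6,9
* arbuscular mycorrhizal fungi (AMF): 16:1w5 — kept separate from the fungal
  group everywhere except multivariate exports
* actinobacteria: 10Me16:0, 10Me17:0, 10Me18:0 — counted inside the
  gram-positive *sum* via a flag
* gram-positive: i15:0, a15:0, i16:0, i17:0, a17:0
* gram-negative: 16:1w7, cy17:0, cy19:0
* general (not group-assignable): 18:1w9t, 16:0, 17:0, 18:0

Marker names are normalization-tolerant: spacing, case, omega-vs-w and
cis/trans spelling variants all resolve to the same canonical name. Unknown
markers fall into the general group with a logged notice.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources

from .errors import VaporSipError
from .types import Group

logger = logging.getLogger(__name__)

__all__ = ["MarkerAssignment", "MarkerRegistry", "default_registry", "normalize_marker"]


def normalize_marker(name: str) -> str:
    """Canonicalize a marker name: strip spaces, omega->w, cis/trans->c/t.

    Prefix tokens (i/a/cy/10Me) and the carbon:double-bond core are preserved.
    """
    if not name or not name.strip():
        raise VaporSipError("empty marker name")
    s = name.strip().replace(" ", "").replace("ω", "w").replace("Ω", "w")
    s = s.replace("cis", "c").replace("trans", "t").lower()
    if s.startswith("10me"):
        s = "10Me" + s[4:]
    return s


@dataclass(frozen=True)
class MarkerAssignment:
    marker: str
    group: Group
    in_gram_positive_sum: bool
    in_multivariate_fungi: bool

    def __post_init__(self):
        if self.group is Group.ACTINOBACTERIA and not self.in_gram_positive_sum:
            raise VaporSipError("actinobacteria markers must count in the gram-positive sum")


class MarkerRegistry:
    """Lookup table from marker name to group, with flag logic for sums."""

    def __init__(self, assignments: list[MarkerAssignment]):
        self._by_name: dict[str, MarkerAssignment] = {}
        for a in assignments:
            key = normalize_marker(a.marker)
            if key in self._by_name:
                raise VaporSipError(f"duplicate marker '{a.marker}' in registry")
            self._by_name[key] = a

    @classmethod
    def from_csv(cls, path_or_file) -> "MarkerRegistry":
        if hasattr(path_or_file, "read"):
            rows = list(csv.DictReader(path_or_file))
        else:
            with open(path_or_file, newline="") as fh:
                rows = list(csv.DictReader(fh))
        assignments = [
            MarkerAssignment(
                marker=r["marker"],
                group=Group(r["group"]),
                in_gram_positive_sum=r["in_gram_positive_sum"].strip().lower() == "true",
                in_multivariate_fungi=r["in_multivariate_fungi"].strip().lower() == "true",
            )
            for r in rows
        ]
        return cls(assignments)

    def assign(self, marker: str) -> MarkerAssignment:
        """Group assignment for a marker; unknown markers -> general, logged."""
        key = normalize_marker(marker)
        if key in self._by_name:
            return self._by_name[key]
        logger.info("marker %r not in registry; assigned to general group", marker)
        return MarkerAssignment(
            marker=key, group=Group.GENERAL,
            in_gram_positive_sum=False, in_multivariate_fungi=False,
        )

    def group_members(self, group: Group) -> set[str]:
        """Canonical marker names assigned to ``group`` (inverse of assign)."""
        return {k for k, a in self._by_name.items() if a.group is group}

    def gram_positive_sum_members(self) -> set[str]:
        """Markers entering gram-positive *sums*: gram-positive + actinobacteria."""
        return {k for k, a in self._by_name.items() if a.in_gram_positive_sum}

    def multivariate_fungi_members(self) -> set[str]:
        """Fungal set for multivariate exports (fungi plus the AMF marker)."""
        return {k for k, a in self._by_name.items() if a.in_multivariate_fungi}

    @property
    def markers(self) -> set[str]:
        return set(self._by_name)

    def __contains__(self, marker: str) -> bool:
        return normalize_marker(marker) in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)


def default_registry() -> MarkerRegistry:
    """The frozen baseline registry shipped with the package."""
    ref = resources.files("vaporsip").joinpath("data/marker_registry.csv")
    with ref.open("r", newline="") as fh:
        return MarkerRegistry.from_csv(fh)
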