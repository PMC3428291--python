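"""Versioned catalog of DRM activity codes.

The abbreviated DRM codes each episode's activity against a fixed list of
22 everyday activities (eating, rest, religious activity, working, ...).
The catalog ships as a TSV resource so the code list can be versioned
independently of the software; each entry carries the activity label, a
baseline reporting weight (percent of respondents mentioning it, used by
the synthetic cohort generator) and a net-affect offset on the latent
affect scale (how much more or less pleasant the activity is than the
average episode).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

CATALOG_VERSION = 1


@dataclass(frozen=True)
class ActivityEntry:
    code: str
    label: str
    weight_pct: float
    net_offset: float


@lru_cache(maxsize=1)
def load_catalog() -> dict[str, ActivityEntry]:
    """Load the activity catalog keyed by activity code (insertion-ordered)."""
    text = resources.files("drmkit.data").joinpath("activities.tsv").read_text()
    entries: dict[str, ActivityEntry] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, label, weight, offset = line.split("\t")
        entries[code] = ActivityEntry(code, label, float(weight), float(offset))
    if len(entries) != 22:
        raise RuntimeError(f"activity catalog corrupt: {len(entries)} entries")
    return entries


def activity_codes() -> tuple[str, ...]:
    return tuple(load_catalog())


def is_known_activity(code: str) -> bool:
    return code in load_catalog()
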