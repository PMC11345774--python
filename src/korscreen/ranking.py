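"""Ranked screening results: the ordered, optionally labeled score list that
both screening engines emit and the validation statistics consume."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

LABELS = ("active", "decoy", "unknown")


@dataclass
class ScreenEntry:
    id: str
    score: float
    label: str = "unknown"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class RankedScreen:
    """Entries ordered by score descending, ties broken by id ascending."""

    entries: list[ScreenEntry]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (-e.score, e.id))
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in ranked screen")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def top(self, n: int) -> "RankedScreen":
        return RankedScreen(list(self.entries[:n]))

    def scores(self) -> list[float]:
        return [e.score for e in self.entries]

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def relabel(self, label_by_id: dict[str, str]) -> "RankedScreen":
        return RankedScreen(
            [
                ScreenEntry(e.id, e.score, label_by_id.get(e.id, e.label), dict(e.extras))
                for e in self.entries
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, e in enumerate(self.entries, start=1):
            rows.append({"rank": rank, "id": e.id, "score": e.score, "label": e.label, **e.extras})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedScreen":
        df = pd.read_csv(path, sep="\t")
        extras_cols = [c for c in df.columns if c not in {"rank", "id", "score", "label"}]
        entries = [
            ScreenEntry(
                str(row["id"]),
                float(row["score"]),
                str(row.get("label", "unknown")) if "label" in df.columns else "unknown",
                {c: row[c] for c in extras_cols},
            )
            for _, row in df.iterrows()
        ]
        return cls(entries)


def merge_entries(screens: Iterable[RankedScreen]) -> list[ScreenEntry]:
    out: list[ScreenEntry] = []
    for s in screens:
        out.extend(s.entries)
    return out
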