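"""Study design: sample → (group, time) mapping for one tissue.

The LPS time-course designs analysed here have one control group (PBS,
encoded as time 0) and several post-treatment groups, each with the same
small number of replicates. Groups are ordered by time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class StudyDesign:
    """Maps each sample to its treatment group and time post-treatment.

    Parameters
    ----------
    samples:
        ``sample_id -> (group_label, time_min)``. Every sample belongs to
        exactly one group; each group needs at least two samples for the
        group-comparison statistics downstream.
    tissue:
        Free-text tissue / cell-type label (e.g. ``"cerebral_vessels"``).
    """

    samples: dict[str, tuple[str, int]]
    tissue: str = "tissue"

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("design has no samples")
        counts: dict[str, int] = {}
        for group, _ in self.samples.values():
            counts[group] = counts.get(group, 0) + 1
        small = [g for g, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"groups with fewer than 2 samples: {small}")

    @property
    def groups(self) -> list[str]:
        """Group labels ordered by time (then label, for stability)."""
        seen: dict[str, int] = {}
        for group, t in self.samples.values():
            seen.setdefault(group, t)
        return sorted(seen, key=lambda g: (seen[g], g))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def group_of(self, sample_id: str) -> str:
        return self.samples[sample_id][0]

    def time_of(self, sample_id: str) -> int:
        return self.samples[sample_id][1]

    def time_of_group(self, group: str) -> int:
        for g, t in self.samples.values():
            if g == group:
                return t
        raise KeyError(group)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, (g, _) in self.samples.items() if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "tissue": self.tissue,
                "group_label": [g for g, _ in self.samples.values()],
                "time_min": [t for _, t in self.samples.values()],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        required = {"sample_id", "group_label", "time_min"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        tissue = str(frame["tissue"].iloc[0]) if "tissue" in frame.columns else "tissue"
        samples = {
            str(r.sample_id): (str(r.group_label), int(r.time_min))
            for r in frame.itertuples()
        }
        return cls(samples=samples, tissue=tissue)

    @classmethod
    def read_tsv(cls, path) -> "StudyDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def lps_design(
    times_min=(0, 15, 30, 240), n_replicates: int = 3, tissue: str = "cerebral_vessels"
) -> StudyDesign:
    """Build the canonical LPS time-course design (PBS control at time 0)."""
    samples: dict[str, tuple[str, int]] = {}
    for t in times_min:
        label = "PBS" if t == 0 else f"LPS_{t}min"
        for r in range(1, n_replicates + 1):
            samples[f"{tissue}_{label}_r{r}"] = (label, int(t))
    return StudyDesign(samples=samples, tissue=tissue)
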