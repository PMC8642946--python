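"""Experimental design for the two-parent reciprocal-F1 cross.

The study design crosses two inbred mouse strains, C57BL/6J (``B6``) and
DBA/2J (``D2``), and profiles both reciprocal F1 hybrids: ``B6D2F1``
(B6 mother x D2 father) and ``D2B6F1`` (D2 mother x B6 father).  The two
hybrids are genetically identical on autosomes and differ only in
parent-of-origin, which is what makes the imprinting screen and the
dominance-relatedness structure of this design possible.

A :class:`StrainDesign` records which sample sits in which TMT channel and
carries the genotype/sex metadata every downstream stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES: tuple[str, ...] = ("B6", "D2", "B6D2F1", "D2B6F1")
PARENTS: tuple[str, str] = ("B6", "D2")
HYBRIDS: tuple[str, str] = ("B6D2F1", "D2B6F1")
SEXES: tuple[str, str] = ("F", "M")


@dataclass(frozen=True)
class Sample:
    """One animal / one TMT channel."""

    sample_id: str
    genotype: str
    sex: str
    channel: int


@dataclass(frozen=True)
class StrainDesign:
    """Ordered collection of samples covering the four genotypes.

    Invariants enforced at construction: all four genotypes present, sexes in
    {M, F}, channel indices unique, sample ids unique.
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        genos = {s.genotype for s in self.samples}
        unknown = genos - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotype label(s): {sorted(unknown)}")
        missing = set(GENOTYPES) - genos
        if missing:
            raise ValueError(f"design lacks genotype(s): {sorted(missing)}")
        bad_sex = {s.sex for s in self.samples} - set(SEXES)
        if bad_sex:
            raise ValueError(f"sex labels must be in {SEXES}, got {sorted(bad_sex)}")
        channels = [s.channel for s in self.samples]
        if len(set(channels)) != len(channels):
            raise ValueError("TMT channel indices must be unique")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return len(self.samples)

    def genotypes(self) -> np.ndarray:
        return np.array([s.genotype for s in self.samples])

    def samples_of(self, *genotypes: str) -> list[str]:
        """Sample ids belonging to the given genotype(s), in design order."""
        want = set(genotypes)
        return [s.sample_id for s in self.samples if s.genotype in want]

    def sex_indicator(self) -> np.ndarray:
        """0/1 coding of sex (F = 1, M = 0), in design order."""
        return np.array([1.0 if s.sex == "F" else 0.0 for s in self.samples])

    # -- constructors / serialization --------------------------------------
    @classmethod
    def default(cls, replicates: int = 1) -> "StrainDesign":
        """4 genotypes x 2 sexes x `replicates` animals, one channel each.

        With ``replicates=1`` this is 8 samples, matching an 11-plex TMT run
        with one male and one female animal per strain (n = 2 biological
        replicates per genotype).
        """
        samples = []
        chan = 0
        for geno in GENOTYPES:
            for sex in SEXES:
                for rep in range(1, replicates + 1):
                    sid = f"{geno}_{sex}{rep}" if replicates > 1 else f"{geno}_{sex}"
                    samples.append(Sample(sid, geno, sex, chan))
                    chan += 1
        return cls(tuple(samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "genotype": [s.genotype for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "channel": [s.channel for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StrainDesign":
        required = {"sample_id", "genotype", "sex", "channel"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample metadata missing column(s): {sorted(missing)}")
        return cls(
            tuple(
                Sample(str(r.sample_id), str(r.genotype), str(r.sex), int(r.channel))
                for r in frame.itertuples()
            )
        )


def require_samples(design: StrainDesign, columns: Iterable[str]) -> list[str]:
    """Check that every design sample id appears in `columns`; return ids."""
    cols = set(columns)
    absent = [sid for sid in design.sample_ids if sid not in cols]
    if absent:
        raise ValueError(f"table lacks sample column(s): {absent}")
    return design.sample_ids


def genotype_means(matrix: pd.DataFrame, design: StrainDesign) -> pd.DataFrame:
    """Per-protein mean abundance for each genotype (columns in design order)."""
    require_samples(design, matrix.columns)
    out = {}
    for geno in GENOTYPES:
        out[geno] = matrix[design.samples_of(geno)].mean(axis=1)
    return pd.DataFrame(out)
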