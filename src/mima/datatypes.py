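"""Core per-mutation containers shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EFFECTS = ("missense", "truncating", "nonstop", "inframe_indel", "silent", "other")
DRIVER_CLASSES = ("breast_driver", "other_driver", "none")


@dataclass(frozen=True)
class MutationRecord:
    """A somatic mutation observed in one case, annotated with gene/effect/context.

    ``trinucleotide_context`` is the reference-strand 3-mer centred on ``pos``;
    its middle base must equal ``ref``.
    """

    case_id: str
    mutation_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    trinucleotide_context: str
    driver_class: str = "none"
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) for {self.mutation_id}")
        ctx = self.trinucleotide_context
        if len(ctx) != 3 or ctx[1] != self.ref:
            raise ValueError(
                f"context {ctx!r} middle base must equal ref {self.ref!r} "
                f"for {self.mutation_id}"
            )
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.driver_class not in DRIVER_CLASSES:
            raise ValueError(f"unknown driver_class {self.driver_class!r}")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class PresenceMatrix:
    """Per-case binary presence of mutations across metastases with read support.

    All four frames are indexed by mutation_id (rows) x sample_id (columns).
    ``vaf`` equals alt/depth wherever depth > 0.
    """

    presence: pd.DataFrame
    vaf: pd.DataFrame = field(default=None)
    depth: pd.DataFrame = field(default=None)
    alt: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.presence = self.presence.astype(bool)
        if not self.presence.any(axis=1).all():
            orphans = self.presence.index[~self.presence.any(axis=1)].tolist()
            raise ValueError(f"mutations present in no sample: {orphans[:5]}")
        for name in ("vaf", "depth", "alt"):
            frame = getattr(self, name)
            if frame is not None and (
                not frame.index.equals(self.presence.index)
                or not frame.columns.equals(self.presence.columns)
            ):
                raise ValueError(f"{name} frame not aligned with presence matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.presence.index)

    @classmethod
    def from_reads(
        cls,
        alt: pd.DataFrame,
        depth: pd.DataFrame,
        min_alt_reads: int = 3,
        min_vaf: float = 0.02,
    ) -> "PresenceMatrix":
        """Call presence from read counts: alt reads >= 3 AND VAF >= 0.02 (configurable).

        Mutations called in no sample are dropped.
        """
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = (alt / depth).where(depth > 0, 0.0)
        presence = (alt >= min_alt_reads) & (vaf >= min_vaf)
        keep = presence.any(axis=1)
        return cls(
            presence=presence.loc[keep],
            vaf=vaf.loc[keep],
            depth=depth.loc[keep],
            alt=alt.loc[keep],
        )
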