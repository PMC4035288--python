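"""Directional set-algebraic integration of expression, CNA and miRNA calls.

Stage II intersects the G1-vs-G3 differential-expression calls with the
grade-wise copy-number sets: genes up in G3 that are amplified in G3,
genes down in G3 that are deleted in G3, and the mirrored G1-side sets
(a gene "up in G1" is read off the single contrast as "down in G3").

Stage III further intersects each stage-II set with the targets of
oppositely-directed miRNAs, yielding four classes:

    class 1: down-in-G3, deleted-in-G3 genes targeted by up-in-G3 miRNAs
    class 2: up-in-G1, amplified-in-G1 genes targeted by down-in-G1 miRNAs
    class 3: up-in-G3, amplified-in-G3 genes targeted by down-in-G3 miRNAs
    class 4: down-in-G1, deleted-in-G1 genes targeted by up-in-G1 miRNAs

The gene signature is the union of the class gene sets and the miRNA
signature the union of the class miRNA sets (a gene or miRNA may appear
in more than one class; unions deduplicate).  Signature downsizing
keeps the candidate genes present in the union of reference signatures,
with a per-reference membership report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .diffexpr import DifferentialResult
from .io import TargetMap

__all__ = ["StageIISets", "SignatureClasses", "Signature", "stage2_sets", "stage3_classes", "downsize_signature"]

log = logging.getLogger(__name__)


@dataclass
class StageIISets:
    up_amplified_g1: set
    down_deleted_g1: set
    up_amplified_g3: set
    down_deleted_g3: set

    def __post_init__(self) -> None:
        if self.up_amplified_g1 & self.down_deleted_g1:
            raise ValueError("a gene cannot be both up and down in G1")
        if self.up_amplified_g3 & self.down_deleted_g3:
            raise ValueError("a gene cannot be both up and down in G3")

    @property
    def union_genes(self) -> set:
        return (
            self.up_amplified_g1
            | self.down_deleted_g1
            | self.up_amplified_g3
            | self.down_deleted_g3
        )


@dataclass
class SignatureClasses:
    """The four (gene set, miRNA set) classes and their derived unions."""

    class1: tuple[set, set]
    class2: tuple[set, set]
    class3: tuple[set, set]
    class4: tuple[set, set]

    @property
    def gene_signature(self) -> set:
        return self.class1[0] | self.class2[0] | self.class3[0] | self.class4[0]

    @property
    def mirna_signature(self) -> set:
        return self.class1[1] | self.class2[1] | self.class3[1] | self.class4[1]

    def genes_of(self, k: int) -> set:
        return getattr(self, f"class{k}")[0]

    def mirnas_of(self, k: int) -> set:
        return getattr(self, f"class{k}")[1]


@dataclass
class Signature:
    name: str
    genes: set

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        self.genes = set(self.genes)


def stage2_sets(
    de: DifferentialResult,
    cna_g1: tuple[set, set],
    cna_g3: tuple[set, set],
) -> StageIISets:
    """Intersect G1-vs-G3 expression calls with grade-wise CNA sets.

    ``de`` must be oriented so that "up" means higher in G3.  ``cna_g1``
    and ``cna_g3`` are (amplified, deleted) gene-set pairs.
    """
    if de.contrast is not None and {de.contrast.class_a, de.contrast.class_b} != {"G1", "G3"}:
        raise ValueError(f"expected a G1/G3 contrast, got {de.contrast}")
    up_g3 = de.up          # higher in G3
    up_g1 = de.down        # higher in G1
    amp_g1, del_g1 = cna_g1
    amp_g3, del_g3 = cna_g3
    return StageIISets(
        up_amplified_g1=up_g1 & amp_g1,
        down_deleted_g1=up_g3 & del_g1,
        up_amplified_g3=up_g3 & amp_g3,
        down_deleted_g3=up_g1 & del_g3,
    )


def stage3_classes(
    stage2: StageIISets,
    mirna_de: DifferentialResult,
    targets: TargetMap,
) -> SignatureClasses:
    """Intersect stage-II sets with targets of oppositely-directed miRNAs.

    ``mirna_de`` must share the G1-vs-G3 orientation of the mRNA
    contrast ("up" = higher in G3).  A class miRNA is one whose call
    matches the class direction and whose target set intersects the
    class genes.  An empty target map yields empty classes (warning).
    """
    if not targets:
        log.warning("empty target map: all signature classes will be empty")
    mir_up_g3 = mirna_de.up        # up in G3 == down in G1
    mir_down_g3 = mirna_de.down    # down in G3 == up in G1

    def build(genes: set, mirnas: set) -> tuple[set, set]:
        covered = set()
        class_mirnas = set()
        for m in mirnas:
            hit = targets.get(m, set()) & genes
            if hit:
                covered |= hit
                class_mirnas.add(m)
        return covered, class_mirnas

    class1 = build(stage2.down_deleted_g3, mir_up_g3)
    class2 = build(stage2.up_amplified_g1, mir_up_g3)    # down in G1 = up in G3
    class3 = build(stage2.up_amplified_g3, mir_down_g3)
    class4 = build(stage2.down_deleted_g1, mir_down_g3)  # up in G1 = down in G3
    return SignatureClasses(class1=class1, class2=class2, class3=class3, class4=class4)


def downsize_signature(
    candidate: Signature, references: Sequence[Signature]
) -> tuple[Signature, dict]:
    """Keep candidate genes present in the union of reference signatures.

    Returns the downsized signature and a per-gene membership report
    (gene -> list of reference names containing it).  An empty result
    is allowed.
    """
    if not references:
        raise ValueError("at least one reference signature required")
    union = set().union(*(r.genes for r in references))
    kept = candidate.genes & union
    report = {
        g: [r.name for r in references if g in r.genes] for g in sorted(kept)
    }
    return Signature(name=f"{candidate.name}_downsized", genes=kept), report
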