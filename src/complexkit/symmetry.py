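"""Point-group symmetry bookkeeping across unique compositions.

Symmetry detection itself is an upstream input: each assembly may carry a
Schoenflies point-group label (C2, D4, T, O, I, ...) produced by an external
detector.  This module normalises the labels, tabulates their frequency, and
flags compositions whose members disagree — a useful screen for assembly
curation errors.  "C1" and "asymmetric" denote the same thing and are
normalised to "C1"; assemblies without a label are excluded rather than
presumed asymmetric.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import AssemblyInstance, UniqueAssembly

_LABEL_RE = re.compile(r"^(C\d+|D\d+|T|O|I|H)$")


def normalize_label(raw: Optional[str]) -> Optional[str]:
    """Uppercase Schoenflies string; 'asymmetric' becomes 'C1'; None passes."""
    if raw is None:
        return None
    label = raw.strip()
    if not label:
        return None
    if label.lower() in ("asymmetric", "none", "c1"):
        return "C1"
    return label.upper()


def classify_label(label: str) -> str:
    """Family of a normalised label: asymmetric/cyclic/dihedral/cubic/other."""
    if label == "C1":
        return "asymmetric"
    if not _LABEL_RE.match(label):
        return "other"
    if label.startswith("C"):
        return "cyclic"
    if label.startswith("D"):
        return "dihedral"
    if label in ("T", "O", "I"):
        return "cubic"
    return "other"


def symmetry_frequency(assemblies: Sequence[AssemblyInstance]) -> dict:
    """Histogram of point-group labels over labelled assemblies.

    Reports per-label counts plus family totals; cyclic and dihedral
    fractions are taken over symmetric (non-C1) recognised labels.
    """
    histogram: Counter[str] = Counter()
    families: Counter[str] = Counter()
    for a in assemblies:
        label = normalize_label(a.symmetry_label)
        if label is None:
            continue
        histogram[label] += 1
        families[classify_label(label)] += 1
    symmetric = families["cyclic"] + families["dihedral"] + families["cubic"]
    return {
        "histogram": dict(sorted(histogram.items())),
        "families": dict(sorted(families.items())),
        "n_labelled": sum(histogram.values()),
        "n_symmetric": symmetric,
        "cyclic_fraction": (families["cyclic"] / symmetric) if symmetric else 0.0,
        "dihedral_fraction": (families["dihedral"] / symmetric) if symmetric else 0.0,
    }


@dataclass
class CompositionConsistency:
    md5: str
    accession: Optional[str]
    member_labels: list[str]
    is_consistent: bool
    histogram: dict[str, int] = field(default_factory=dict)


@dataclass
class ConsistencyReport:
    """Per-composition symmetry agreement among members.

    Only compositions with at least two labelled members are assessed.
    ``n_assessed``/``n_inconsistent`` count compositions; the member-level
    counting is exposed alongside since either denominator is defensible.
    """

    compositions: list[CompositionConsistency] = field(default_factory=list)
    n_assessed: int = 0
    n_inconsistent: int = 0
    n_members_assessed: int = 0
    n_members_inconsistent: int = 0

    @property
    def fraction_inconsistent(self) -> float:
        return (self.n_inconsistent / self.n_assessed) if self.n_assessed else 0.0

    @property
    def member_fraction_inconsistent(self) -> float:
        if not self.n_members_assessed:
            return 0.0
        return self.n_members_inconsistent / self.n_members_assessed


def consistency_by_composition(
    uniques: Sequence[UniqueAssembly],
    assemblies: Sequence[AssemblyInstance],
) -> ConsistencyReport:
    """Flag unique compositions whose members carry disagreeing labels.

    ``assemblies`` supplies the per-member symmetry labels; members without a
    label are ignored, so adding an unlabelled member never changes a
    composition's status.
    """
    label_of = {a.key: normalize_label(a.symmetry_label) for a in assemblies}
    report = ConsistencyReport()
    for u in uniques:
        labels = [
            lbl for m in u.members if (lbl := label_of.get(m)) is not None
        ]
        if len(labels) < 2:
            continue
        consistent = len(set(labels)) == 1
        report.compositions.append(
            CompositionConsistency(
                md5=u.md5_hex,
                accession=u.accession,
                member_labels=labels,
                is_consistent=consistent,
                histogram=dict(sorted(Counter(labels).items())),
            )
        )
        report.n_assessed += 1
        report.n_members_assessed += len(labels)
        if not consistent:
            report.n_inconsistent += 1
            report.n_members_inconsistent += len(labels)
    return report
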