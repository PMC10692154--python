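"""Synthetic archive snapshots with machine-readable ground truth.

The generator emulates the archetypes an archive-wide assembly pipeline must
handle — homomers, heteromers, Complex-Portal-matching complexes, ribosomes,
antibody complexes, nucleic-acid-only assemblies, Rfam-mapped riboswitches,
chimeric entities and sub/super-assembly pairs — with known intended names,
categories, portal matches, relations and symmetry consistency, so every
pipeline stage is testable without touching live databases.

Synthetic accessions live in reserved fake namespaces (``UPnnnnn`` proteins,
``CPX-9nnnnn`` portal complexes, four-digit entry codes) so no coupling to
real database records is implied.  :func:`reference_examples` is the one
exception: a fixed, non-random bundle replicating well-documented archive
cases (adult haemoglobin and its receptor complex, the CLOCK-BMAL1
heterodimer, cyclin-CDK with its inhibitor, the UV-damage-bound nucleosome,
E. coli ribosomes, antibody Fabs, the SAM riboswitch) with their expected
outputs, using the real accessions.

One seeded pseudo-random generator drives all draws; the same seed always
reproduces the same bundle byte for byte.

A note on multiplicity: components that cannot be mapped to an external
reference are labelled by entry and entity, so compositions containing them
are never shared between entries — their unique groups have exactly one
member, as in the real archive.  The generator therefore emits single-member
groups for archetypes with unmapped components and multi-member groups (the
interesting case for identifier reuse and symmetry consistency) only for
fully mapped compositions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Optional, Union

from .archive_io import write_curated_names, write_portal_catalog, write_snapshot
from .identity import canonical_key
from .models import (
    AssemblyInstance,
    CuratedNameMap,
    PolymerComponent,
    PortalComplex,
)

PathLike = Union[str, Path]


@dataclass
class FixtureConfig:
    """Archetype counts and noise settings for one synthetic archive."""

    homomer: int = 12
    monomer: int = 6
    heteromer: int = 4  # mapped heteromers no rule can name (stay unnamed)
    uniprot_extras: int = 3  # single mapped protein plus DNA
    portal_exact: int = 5
    portal_extended: int = 3
    multi_portal: int = 2
    ribosome_70S: int = 3
    ribosome_SSU: int = 2
    antibody_complex: int = 4
    nucleic_only: int = 5
    rfam_riboswitch: int = 3
    go_complex: int = 4
    curated_complex: int = 3
    entity_named: int = 4
    common_entity: int = 2
    chimeric: int = 3
    sub_super_pair: int = 3
    portal_decoys: int = 5  # catalogue entries matching nothing
    symmetry_noise: float = 0.06  # chance a multi-member group disagrees
    seed: int = 0

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name in ("symmetry_noise",):
                if not 0.0 <= v <= 1.0:
                    raise ValueError("symmetry_noise must be in [0, 1]")
            elif f.name != "seed" and v < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass
class GroupTruth:
    """Intended pipeline outcome for one generated composition."""

    group_id: str
    name: Optional[str]
    category: str
    portal_kind: Optional[str] = None
    portal_acs: tuple[str, ...] = ()
    sub_of: tuple[str, ...] = ()  # group ids this group is a sub-assembly of
    symmetry_consistent: Optional[bool] = None
    excluded: bool = False


@dataclass
class FixtureTruth:
    groups: dict[str, GroupTruth] = field(default_factory=dict)
    assembly_group: dict[tuple[str, int], str] = field(default_factory=dict)

    def group_of(self, member: tuple[str, int]) -> GroupTruth:
        return self.groups[self.assembly_group[member]]


@dataclass
class FixtureBundle:
    assemblies: list[AssemblyInstance]
    portal: list[PortalComplex]
    curated: CuratedNameMap
    truth: FixtureTruth

    def write(self, out_dir: PathLike) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "snapshot": out / "snapshot.tsv",
            "portal": out / "portal.tsv",
            "curated": out / "curated.tsv",
            "truth": out / "truth.tsv",
        }
        write_snapshot(self.assemblies, paths["snapshot"])
        write_portal_catalog(self.portal, paths["portal"])
        write_curated_names(self.curated, paths["curated"])
        lines = ["member\tgroup_id\tname\tcategory\tportal_kind\tportal_acs\tsub_of\tsymmetry_consistent\texcluded"]
        for member, gid in sorted(self.assembly_group_items()):
            g = self.truth.groups[gid]
            lines.append(
                "\t".join(
                    [
                        f"{member[0]}_{member[1]}",
                        gid,
                        g.name or "",
                        g.category,
                        g.portal_kind or "",
                        "|".join(g.portal_acs),
                        "|".join(g.sub_of),
                        "" if g.symmetry_consistent is None else str(g.symmetry_consistent),
                        str(g.excluded),
                    ]
                )
            )
        paths["truth"].write_text("\n".join(lines) + "\n")
        return paths

    def assembly_group_items(self):
        return list(self.truth.assembly_group.items())


class _Generator:
    def __init__(self, config: FixtureConfig):
        config.validate()
        self.config = config
        self.rng = random.Random(config.seed)
        self._entry_n = 0
        self._acc_n = 0
        self._cpx_n = 0
        self.assemblies: list[AssemblyInstance] = []
        self.portal: list[PortalComplex] = []
        self.curated = CuratedNameMap()
        self.truth = FixtureTruth()

    # -- id factories ------------------------------------------------------
    def entry(self) -> str:
        self._entry_n += 1
        if self._entry_n > 8999:
            raise ValueError("fixture generator supports at most 8999 entries")
        return f"{1000 + self._entry_n:04d}"

    def accession(self) -> str:
        self._acc_n += 1
        return f"UP{self._acc_n:05d}"

    def cpx(self) -> str:
        self._cpx_n += 1
        return f"CPX-9{self._cpx_n:05d}"

    # -- group emission ----------------------------------------------------
    def emit_group(
        self,
        group_id: str,
        build: Callable[[str], list[PolymerComponent]],
        *,
        name: Optional[str],
        category: str,
        n_members: int = 1,
        base_symmetry: Optional[str] = None,
        portal_kind: Optional[str] = None,
        portal_acs: tuple[str, ...] = (),
        sub_of: tuple[str, ...] = (),
        excluded: bool = False,
        extra_assembly_scale: Optional[int] = None,
    ) -> GroupTruth:
        perturb = (
            n_members >= 2
            and base_symmetry is not None
            and self.rng.random() < self.config.symmetry_noise
        )
        consistent: Optional[bool]
        if n_members >= 2 and base_symmetry is not None:
            consistent = not perturb
        else:
            consistent = None
        truth = GroupTruth(
            group_id=group_id,
            name=name,
            category=category,
            portal_kind=portal_kind,
            portal_acs=portal_acs,
            sub_of=sub_of,
            symmetry_consistent=consistent,
            excluded=excluded,
        )
        self.truth.groups[group_id] = truth
        for m in range(n_members):
            entry = self.entry()
            components = build(entry)
            label = base_symmetry
            if perturb and m == n_members - 1:
                label = "C1" if base_symmetry != "C1" else "C2"
            asm = AssemblyInstance(entry, 1, components, symmetry_label=label)
            self.assemblies.append(asm)
            self.truth.assembly_group[asm.key] = group_id
            if m == 0 and extra_assembly_scale and extra_assembly_scale > 1:
                bigger = [
                    PolymerComponent(
                        entry_id=c.entry_id,
                        entity_id=c.entity_id,
                        polymer_type=c.polymer_type,
                        copies=c.copies * extra_assembly_scale,
                        uniprot_accessions=c.uniprot_accessions,
                        rfam_accession=c.rfam_accession,
                        is_antibody=c.is_antibody,
                        entity_name=c.entity_name,
                        uniprot_name=c.uniprot_name,
                        go_cc_terms=c.go_cc_terms,
                        taxonomy_id=c.taxonomy_id,
                        seq_length=c.seq_length,
                    )
                    for c in components
                ]
                self.assemblies.append(
                    AssemblyInstance(entry, 2, bigger, symmetry_label=label)
                )
        return truth

    # -- component factory -------------------------------------------------
    def protein(
        self,
        entry: str,
        entity: int,
        acc: Optional[str],
        copies: int,
        name: str = "",
        uniprot_name: Optional[str] = None,
        is_antibody: bool = False,
        go: tuple[tuple[str, str], ...] = (),
        tax: Optional[int] = 562,
        seq_length: Optional[int] = None,
        accessions: Optional[tuple[str, ...]] = None,
    ) -> PolymerComponent:
        return PolymerComponent(
            entry_id=entry,
            entity_id=entity,
            polymer_type="protein",
            copies=copies,
            uniprot_accessions=accessions if accessions is not None else ((acc,) if acc else ()),
            is_antibody=is_antibody,
            entity_name=name,
            uniprot_name=uniprot_name,
            go_cc_terms=go,
            taxonomy_id=tax,
            seq_length=seq_length,
        )

    def nucleic(
        self,
        entry: str,
        entity: int,
        polymer_type: str,
        copies: int,
        rfam: Optional[str] = None,
        name: str = "",
        tax: Optional[int] = 562,
    ) -> PolymerComponent:
        return PolymerComponent(
            entry_id=entry,
            entity_id=entity,
            polymer_type=polymer_type,
            copies=copies,
            rfam_accession=rfam,
            entity_name=name,
            taxonomy_id=tax,
        )

    def md5_of(self, build: Callable[[str], list[PolymerComponent]]) -> str:
        """Digest of a composition as built for a probe entry.

        Only safe for fully mapped compositions, whose labels do not embed
        the entry id.
        """
        probe = AssemblyInstance("0000", 1, build("0000"))
        return canonical_key(probe).md5_hex

    # -- archetypes --------------------------------------------------------
    def run(self) -> FixtureBundle:
        c = self.config
        for i in range(c.homomer):
            acc = self.accession()
            copies = self.rng.choice([2, 3, 4, 6])
            pname = f"Synthetic oligomer protein {i + 1}"

            def build(entry, acc=acc, copies=copies, pname=pname):
                return [self.protein(entry, 1, acc, copies, uniprot_name=pname)]

            self.emit_group(
                f"homomer_{i + 1}",
                build,
                name=pname,
                category="uniprot",
                n_members=self.rng.choice([2, 2, 3]),
                base_symmetry=f"C{copies}" if self.rng.random() < 0.8 else f"D{max(copies // 2, 2)}",
                extra_assembly_scale=2 if i % 3 == 0 else None,
            )

        for i in range(c.monomer):
            acc = self.accession()
            pname = f"Synthetic monomeric enzyme {i + 1}"

            def build(entry, acc=acc, pname=pname):
                return [self.protein(entry, 1, acc, 1, uniprot_name=pname)]

            self.emit_group(
                f"monomer_{i + 1}",
                build,
                name=pname,
                category="uniprot",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
            )

        for i in range(c.heteromer):
            accs = [self.accession() for _ in range(self.rng.choice([2, 3]))]

            def build(entry, accs=accs):
                return [
                    self.protein(entry, k + 1, a, 1, uniprot_name=f"Subunit {a}")
                    for k, a in enumerate(accs)
                ]

            self.emit_group(
                f"heteromer_{i + 1}",
                build,
                name=None,
                category="unnamed",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
            )

        for i in range(c.uniprot_extras):
            acc = self.accession()
            pname = f"Synthetic DNA-binding protein {i + 1}"

            def build(entry, acc=acc, pname=pname):
                return [
                    self.protein(entry, 1, acc, 2, uniprot_name=pname),
                    self.nucleic(entry, 2, "DNA", 1, name="bound duplex DNA"),
                ]

            self.emit_group(
                f"uniprot_extras_{i + 1}",
                build,
                name=f"{pname}, DNA complex",
                category="uniprot",
                n_members=1,
                base_symmetry="C1",
            )

        for i in range(c.portal_exact):
            accs = [self.accession(), self.accession()]
            cpx_ac = self.cpx()
            cpx_name = f"Synthetic portal complex {i + 1}"
            self.portal.append(
                PortalComplex(cpx_ac, cpx_name, tuple((a, 1) for a in accs))
            )

            def build(entry, accs=accs):
                return [
                    self.protein(entry, k + 1, a, 1, uniprot_name=f"Portal subunit {a}")
                    for k, a in enumerate(accs)
                ]

            self.emit_group(
                f"portal_exact_{i + 1}",
                build,
                name=cpx_name,
                category="complex_portal",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
                portal_kind="exact",
                portal_acs=(cpx_ac,),
            )

        for i in range(c.portal_extended):
            accs = [self.accession(), self.accession()]
            extra_acc = self.accession()
            extra_name = f"Extension factor {i + 1}"
            cpx_ac = self.cpx()
            cpx_name = f"Synthetic core complex {i + 1}"
            self.portal.append(
                PortalComplex(cpx_ac, cpx_name, tuple((a, 1) for a in accs))
            )

            def build(entry, accs=accs, extra_acc=extra_acc, extra_name=extra_name):
                comps = [
                    self.protein(entry, k + 1, a, 1, uniprot_name=f"Core subunit {a}")
                    for k, a in enumerate(accs)
                ]
                comps.append(
                    self.protein(entry, 3, extra_acc, 1, uniprot_name=extra_name)
                )
                return comps

            self.emit_group(
                f"portal_extended_{i + 1}",
                build,
                name=f"{cpx_name} and {extra_name}",
                category="complex_portal",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
                portal_kind="exact_plus_extras",
                portal_acs=(cpx_ac,),
            )

        for i in range(c.multi_portal):
            accs1 = [self.accession(), self.accession()]
            accs2 = [self.accession(), self.accession()]
            ac1, ac2 = self.cpx(), self.cpx()
            n1 = f"Synthetic octameric machine {i + 1}"
            n2 = f"Synthetic recognition module {i + 1}"
            self.portal.append(PortalComplex(ac1, n1, tuple((a, 2) for a in accs1)))
            self.portal.append(PortalComplex(ac2, n2, tuple((a, 1) for a in accs2)))

            def build(entry, accs1=accs1, accs2=accs2):
                comps = [
                    self.protein(entry, k + 1, a, 2, uniprot_name=f"Machine subunit {a}")
                    for k, a in enumerate(accs1)
                ]
                comps += [
                    self.protein(entry, len(accs1) + k + 1, a, 1, uniprot_name=f"Module subunit {a}")
                    for k, a in enumerate(accs2)
                ]
                comps.append(self.nucleic(entry, 5, "DNA", 1, name="substrate DNA"))
                return comps

            self.emit_group(
                f"multi_portal_{i + 1}",
                build,
                name=f"{n1} and {n2} and DNA",
                category="complex_portal",
                n_members=1,
                base_symmetry="C1",
                portal_kind="multi_portal",
                portal_acs=(ac1, ac2),
            )

        for i in range(c.ribosome_70S):
            variant = i % 3  # 0 bare, 1 +tRNA, 2 +tRNA +mRNA
            prot_accs = [self.accession() for _ in range(3)]
            prot_names = [
                "30S ribosomal protein S3",
                "50S ribosomal protein L2",
                "50S ribosomal protein L4",
            ]

            def build(entry, prot_accs=prot_accs, prot_names=prot_names, variant=variant):
                comps = [
                    self.nucleic(entry, 1, "RNA", 1, rfam="RF00177", name="16S rRNA"),
                    self.nucleic(entry, 2, "RNA", 1, rfam="RF02541", name="23S rRNA"),
                    self.nucleic(entry, 3, "RNA", 1, rfam="RF00001", name="5S rRNA"),
                ]
                comps += [
                    self.protein(entry, 4 + k, a, 1, uniprot_name=n)
                    for k, (a, n) in enumerate(zip(prot_accs, prot_names))
                ]
                if variant >= 1:
                    comps.append(
                        self.nucleic(entry, 7, "RNA", 1, rfam="RF00005", name="tRNA")
                    )
                if variant == 2:
                    comps.append(self.nucleic(entry, 8, "RNA", 1, name="mRNA"))
                return comps

            name = "70 S ribosome" + (" and tRNA" if variant >= 1 else "") + (
                " and RNA" if variant == 2 else ""
            )
            self.emit_group(
                f"ribosome_70S_{i + 1}",
                build,
                name=name,
                category="ribosome",
                n_members=1 if variant == 2 else self.rng.choice([1, 2]),
                base_symmetry="C1",
            )

        for i in range(c.ribosome_SSU):
            prot_accs = [self.accession() for _ in range(2)]

            def build(entry, prot_accs=prot_accs):
                comps = [
                    self.nucleic(entry, 1, "RNA", 1, rfam="RF00177", name="16S rRNA")
                ]
                comps += [
                    self.protein(
                        entry, 2 + k, a, 1,
                        uniprot_name=f"30S ribosomal protein S{k + 2}",
                    )
                    for k, a in enumerate(prot_accs)
                ]
                return comps

            self.emit_group(
                f"ribosome_SSU_{i + 1}",
                build,
                name="30 S ribosomal subunit",
                category="ribosome",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
            )

        for i in range(c.antibody_complex):
            light = "IG-light kappa chain" if i % 2 == 0 else "IG-light lambda chain"

            def build(entry, light=light):
                return [
                    self.protein(entry, 1, None, 1, name="IG-heavy chain", is_antibody=True, tax=9606),
                    self.protein(entry, 2, None, 1, name=light, is_antibody=True, tax=9606),
                ]

            self.emit_group(
                f"antibody_{i + 1}",
                build,
                name=f"IG-heavy chain and {light}",
                category="antibody",
                n_members=1,
                base_symmetry="C1",
            )

        for i in range(c.nucleic_only):
            ptype = ["DNA", "RNA", "DNA/RNA"][i % 3]
            generic = {"DNA": "DNA", "RNA": "RNA", "DNA/RNA": "DNA/RNA hybrid"}[ptype]
            copies = self.rng.choice([1, 2])

            def build(entry, ptype=ptype, copies=copies):
                return [self.nucleic(entry, 1, ptype, copies, name=f"synthetic {ptype} strand")]

            self.emit_group(
                f"nucleic_{i + 1}",
                build,
                name=generic,
                category="nucleic_generic",
                n_members=1,
                base_symmetry=None,
            )

        riboswitch_families = [
            ("RF00162", "SAM riboswitch"),
            ("RF00010", "RNase P RNA"),
            ("RF00028", "group-I intron"),
        ]
        for i in range(c.rfam_riboswitch):
            fam, fam_name = riboswitch_families[i % len(riboswitch_families)]
            copies = 1 + i // len(riboswitch_families)

            def build(entry, fam=fam, copies=copies):
                return [self.nucleic(entry, 1, "RNA", copies, rfam=fam, name=fam_name)]

            self.emit_group(
                f"rfam_{i + 1}",
                build,
                name=fam_name,
                category="rfam",
                n_members=self.rng.choice([1, 2]),
                base_symmetry=None,
            )

        go_terms = [
            ("GO:0000502", "proteasome complex"),
            ("GO:0009522", "photosystem I"),
            ("GO:0009523", "photosystem II"),
            ("GO:0033178", "proton-transporting two-sector ATPase complex"),
        ]
        for i in range(c.go_complex):
            go_id, go_name = go_terms[i % len(go_terms)]
            accs = [self.accession() for _ in range(self.rng.choice([2, 3]))]

            def build(entry, accs=accs, go_id=go_id, go_name=go_name):
                return [
                    self.protein(
                        entry, k + 1, a, self.rng.choice([1, 2]),
                        uniprot_name=f"Component {a}",
                        go=((go_id, go_name), ("GO:0005737", "cytoplasm")),
                    )
                    for k, a in enumerate(accs)
                ]

            self.emit_group(
                f"go_{i + 1}",
                build,
                name=go_name,
                category="go",
                n_members=1,
                base_symmetry="C1",
            )

        for i in range(c.curated_complex):
            accs = [self.accession(), self.accession()]

            def build(entry, accs=accs):
                return [
                    self.protein(entry, k + 1, a, 1, uniprot_name=f"Curated subunit {a}")
                    for k, a in enumerate(accs)
                ]

            name = f"Synthetic curated complex {i + 1}"
            self.curated.entries[self.md5_of(build)] = name
            self.emit_group(
                f"curated_{i + 1}",
                build,
                name=name,
                category="curated",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C1",
            )

        for i in range(c.entity_named):
            ename = f"synthetic unmapped enzyme {i + 1}"

            def build(entry, ename=ename):
                return [self.protein(entry, 1, None, 2, name=ename)]

            self.emit_group(
                f"entity_{i + 1}",
                build,
                name=ename,
                category="unmapped_protein",
                n_members=1,
                base_symmetry="C2",
            )

        for i in range(c.common_entity):
            ename = f"synthetic channel subunit {i + 1}"

            def build(entry, ename=ename):
                return [
                    self.protein(entry, 1, None, 2, name=ename),
                    self.protein(entry, 2, None, 2, name=ename),
                ]

            self.emit_group(
                f"common_entity_{i + 1}",
                build,
                name=ename,
                category="entity_common_name",
                n_members=1,
                base_symmetry="C2",
            )

        for i in range(c.chimeric):
            accs = (self.accession(), self.accession())

            def build(entry, accs=accs):
                return [
                    self.protein(
                        entry, 1, None, 1,
                        name="engineered fusion protein",
                        accessions=accs,
                    )
                ]

            self.emit_group(
                f"chimeric_{i + 1}",
                build,
                name=None,
                category="excluded",
                n_members=1,
                base_symmetry=None,
                excluded=True,
            )

        for i in range(c.sub_super_pair):
            acc_a, acc_b, acc_c = self.accession(), self.accession(), self.accession()

            def build_sub(entry, a=acc_a, b=acc_b):
                return [
                    self.protein(entry, 1, a, 2, uniprot_name=f"Core alpha {a}"),
                    self.protein(entry, 2, b, 2, uniprot_name=f"Core beta {b}"),
                ]

            def build_super(entry, a=acc_a, b=acc_b, cc=acc_c):
                return build_sub(entry, a, b) + [
                    self.protein(entry, 3, cc, 2, uniprot_name=f"Receptor {cc}")
                ]

            sub_name = f"Synthetic core pair {i + 1}"
            super_name = f"Synthetic core pair {i + 1} receptor complex"
            self.curated.entries[self.md5_of(build_sub)] = sub_name
            self.curated.entries[self.md5_of(build_super)] = super_name
            super_truth = self.emit_group(
                f"super_{i + 1}",
                build_super,
                name=super_name,
                category="curated",
                n_members=1,
                base_symmetry="C2",
            )
            self.emit_group(
                f"sub_{i + 1}",
                build_sub,
                name=sub_name,
                category="curated",
                n_members=self.rng.choice([1, 2]),
                base_symmetry="C2",
                sub_of=(super_truth.group_id,),
            )

        for i in range(c.portal_decoys):
            accs = [self.accession(), self.accession()]
            self.portal.append(
                PortalComplex(
                    self.cpx(), f"Synthetic decoy complex {i + 1}", tuple((a, 1) for a in accs)
                )
            )

        return FixtureBundle(self.assemblies, self.portal, self.curated, self.truth)


def generate_archive(config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Generate one synthetic archive with ground truth (seed-deterministic)."""
    return _Generator(config or FixtureConfig()).run()


# ---------------------------------------------------------------------------
# fixed replica bundle


def reference_examples() -> FixtureBundle:
    """Fixed bundle replicating well-documented archive cases.

    Covers adult haemoglobin (and the IsdB receptor super-assembly), the
    HslV-HslU hexamer/dodecamer preferred-assembly case, the CLOCK-BMAL1
    Complex Portal exact match, cyclin A2-CDK2 with its inhibitor (portal
    match with an extra component), the UV-damage nucleosome mapping to two
    portal complexes, an interleukin-17A Fab complex, an antibody-only Fab,
    an unmapped homomer, an RNA-polymerase-II GO-named dimer, bacterial
    ribosomes (70 S, 30 S, tRNA/mRNA-bound and a no-Rfam fallback case), the
    SAM riboswitch, a stoichiometry-variable homomer group and a
    symmetry-inconsistent histidine-kinase dimer group.
    """
    assemblies: list[AssemblyInstance] = []
    portal: list[PortalComplex] = []
    curated = CuratedNameMap()
    truth = FixtureTruth()

    def P(entry, entity, acc, copies, uniprot_name=None, name="", antibody=False,
          go=(), tax=9606, seq_length=None, accessions=None):
        return PolymerComponent(
            entry_id=entry, entity_id=entity, polymer_type="protein", copies=copies,
            uniprot_accessions=accessions if accessions is not None else ((acc,) if acc else ()),
            is_antibody=antibody, entity_name=name, uniprot_name=uniprot_name,
            go_cc_terms=tuple(go), taxonomy_id=tax, seq_length=seq_length,
        )

    def N(entry, entity, ptype, copies, rfam=None, name="", tax=562):
        return PolymerComponent(
            entry_id=entry, entity_id=entity, polymer_type=ptype, copies=copies,
            rfam_accession=rfam, entity_name=name, taxonomy_id=tax,
        )

    def add(entry, assembly_id, components, group, symmetry=None):
        asm = AssemblyInstance(entry, assembly_id, components, symmetry_label=symmetry)
        assemblies.append(asm)
        truth.assembly_group[asm.key] = group
        return asm

    def group(gid, name, category, **kw):
        truth.groups[gid] = GroupTruth(group_id=gid, name=name, category=category, **kw)

    hb_go = (("GO:0005833", "haemoglobin complex"),)
    hb = lambda e: [
        P(e, 1, "P69905", 2, "Hemoglobin subunit alpha", go=hb_go),
        P(e, 2, "P68871", 2, "Hemoglobin subunit beta", go=hb_go),
    ]
    group("haemoglobin", "haemoglobin complex", "go",
          sub_of=("haemoglobin_isdb",), symmetry_consistent=True)
    add("6kat", 1, hb("6kat"), "haemoglobin", symmetry="C2")
    add("7jy3", 1, hb("7jy3"), "haemoglobin", symmetry="C2")
    group("haemoglobin_isdb", None, "unnamed")
    add("7pch", 1, hb("7pch") + [P("7pch", 3, "Q8NX66", 2, "Iron-regulated surface determinant protein B")],
        "haemoglobin_isdb")

    # preferred-assembly case: hexamer vs dodecamer of the same entity
    group("hslv", "ATP-dependent protease subunit HslV", "uniprot")
    add("1e94", 1, [P("1e94", 1, "P0A7B8", 6, "ATP-dependent protease subunit HslV", tax=83333)],
        "hslv", symmetry="C6")
    add("1e94", 2, [P("1e94", 1, "P0A7B8", 12, "ATP-dependent protease subunit HslV", tax=83333)],
        "hslv", symmetry="D6")

    portal.append(PortalComplex("CPX-3225", "CLOCK-Bmal1 transcription complex",
                                (("Q9WTL8", 1), ("O08785", 1))))
    group("clock_bmal1", "CLOCK-Bmal1 transcription complex", "complex_portal",
          portal_kind="exact", portal_acs=("CPX-3225",))
    add("4f3l", 1, [
        P("4f3l", 1, "O08785", 1, "Circadian locomoter output cycles protein kaput", tax=10090),
        P("4f3l", 2, "Q9WTL8", 1, "Aryl hydrocarbon receptor nuclear translocator-like protein 1", tax=10090),
    ], "clock_bmal1", symmetry="C1")

    portal.append(PortalComplex("CPX-2006", "Cyclin A2-CK2 complex",
                                (("P20248", 1), ("P24941", 1))))
    group("cyclin_cdk_inhibitor", "Cyclin A2-CK2 complex and Cyclin-dependent kinase inhibitor 1B",
          "complex_portal", portal_kind="exact_plus_extras", portal_acs=("CPX-2006",))
    add("1h27", 1, [
        P("1h27", 1, "P20248", 1, "Cyclin-A2"),
        P("1h27", 2, "P24941", 1, "Cyclin-dependent kinase 2"),
        P("1h27", 3, "P46527", 1, "Cyclin-dependent kinase inhibitor 1B"),
    ], "cyclin_cdk_inhibitor", symmetry="C1")

    portal.append(PortalComplex("CPX-2556", "Nucleosome variant H3.1-H2A.2-H2B.1",
                                (("P68431", 2), ("P62805", 2), ("Q6FI13", 2), ("P33778", 2))))
    portal.append(PortalComplex("CPX-308", "UV DNA damage recognition complex DDB1-DDB2",
                                (("Q16531", 1), ("Q92466", 1))))
    group("nucleosome_uvddb", None, "complex_portal",
          portal_kind="multi_portal", portal_acs=("CPX-2556", "CPX-308"))
    add("6r8z", 1, [
        P("6r8z", 1, "P68431", 2, "Histone H3.1"),
        P("6r8z", 2, "P62805", 2, "Histone H4"),
        P("6r8z", 3, "Q6FI13", 2, "Histone H2A type 2-A"),
        P("6r8z", 4, "P33778", 2, "Histone H2B type 1-B"),
        P("6r8z", 5, "Q16531", 1, "DNA damage-binding protein 1"),
        P("6r8z", 6, "Q92466", 1, "DNA damage-binding protein 2"),
        N("6r8z", 7, "DNA", 2, name="nucleosomal DNA", tax=9606),
    ], "nucleosome_uvddb")
    # the multi-portal name is assembled from the two portal names plus DNA
    truth.groups["nucleosome_uvddb"].name = (
        "Nucleosome variant H3.1-H2A.2-H2B.1 and UV DNA damage recognition complex DDB1-DDB2 and DNA"
    )

    group("il17_fab", "Interleukin-17A, IG-heavy chain, IG-light lambda chain, peptide complex",
          "uniprot")
    add("5hi4", 1, [
        P("5hi4", 1, "Q16552", 2, "Interleukin-17A", seq_length=155),
        P("5hi4", 2, None, 2, name="IG-heavy chain", antibody=True, seq_length=220),
        P("5hi4", 3, None, 2, name="IG-light lambda chain", antibody=True, seq_length=214),
        P("5hi4", 4, None, 2, name="HAP peptide", seq_length=12),
    ], "il17_fab", symmetry="C2")

    group("fab_12e8", "IG-heavy chain and IG-light kappa chain", "antibody")
    add("12e8", 1, [
        P("12e8", 1, None, 2, name="IG-heavy chain", antibody=True, tax=10090),
        P("12e8", 2, None, 2, name="IG-light kappa chain", antibody=True, tax=10090),
    ], "fab_12e8", symmetry="C2")

    group("unmapped_homomer", "dihydrolipoamide dehydrogenase", "unmapped_protein")
    add("1ivi", 1, [P("1ivi", 1, None, 2, name="dihydrolipoamide dehydrogenase", tax=None)],
        "unmapped_homomer", symmetry="C2")

    pol2_go = (("GO:0016591", "DNA-directed RNA Polymerase II"), ("GO:0005634", "nucleus"))
    group("rna_pol_ii", "DNA-directed RNA Polymerase II", "go")
    add("2c35", 1, [
        P("2c35", 1, "P20433", 1, "DNA-directed RNA polymerase II subunit RPB4", go=pol2_go, tax=559292),
        P("2c35", 2, "P34087", 1, "DNA-directed RNA polymerase II subunit RPB7", go=pol2_go, tax=559292),
    ], "rna_pol_ii", symmetry="C1")

    def ribosome_core(e, with_trna=False, with_mrna=False):
        comps = [
            N(e, 1, "RNA", 1, rfam="RF00177", name="16S ribosomal RNA"),
            N(e, 2, "RNA", 1, rfam="RF02541", name="23S ribosomal RNA"),
            N(e, 3, "RNA", 1, rfam="RF00001", name="5S ribosomal RNA"),
            P(e, 4, "P0A7V0", 1, "30S ribosomal protein S2", tax=562),
            P(e, 5, "P60422", 1, "50S ribosomal protein L2", tax=562),
            P(e, 6, "P60438", 1, "50S ribosomal protein L3", tax=562),
        ]
        if with_trna:
            comps.append(N(e, 7, "RNA", 2, rfam="RF00005", name="tRNA"))
        if with_mrna:
            comps.append(N(e, 8, "RNA", 1, name="mRNA"))
        return comps

    group("ribosome_70s", "70 S ribosome", "ribosome")
    add("5j7l", 1, ribosome_core("5j7l"), "ribosome_70s")
    group("ribosome_70s_trna_mrna", "70 S ribosome and tRNA and RNA", "ribosome")
    add("6bok", 1, ribosome_core("6bok", with_trna=True, with_mrna=True), "ribosome_70s_trna_mrna")
    group("ribosome_30s", "30 S ribosomal subunit", "ribosome")
    add("6v3e", 1, [
        N("6v3e", 1, "RNA", 1, rfam="RF00177", name="16S ribosomal RNA"),
        P("6v3e", 2, "P0A7V0", 1, "30S ribosomal protein S2", tax=562),
        P("6v3e", 3, "P0A7W1", 1, "30S ribosomal protein S5", tax=562),
    ], "ribosome_30s")
    # fallback route: unmapped RNA + ribosomal proteins, no Rfam mapping
    group("ribosome_fallback", "50 S ribosomal subunit", "ribosome")
    add("8rbf", 1, [
        N("8rbf", 1, "RNA", 1, name="large subunit rRNA"),
        P("8rbf", 2, "P60422", 1, "50S ribosomal protein L2", tax=562),
    ], "ribosome_fallback")

    group("sam_riboswitch", "SAM riboswitch", "rfam")
    add("2gis", 1, [N("2gis", 1, "RNA", 1, rfam="RF00162", name="SAM-I riboswitch", tax=None)],
        "sam_riboswitch")

    # stoichiometry-variable homomer: one tetramer annotation among dimers
    group("kat2_dimer", "Kynurenine/alpha-aminoadipate aminotransferase, mitochondrial", "uniprot",
          symmetry_consistent=True)
    group("kat2_tetramer", "Kynurenine/alpha-aminoadipate aminotransferase, mitochondrial", "uniprot")
    kat = lambda e, n: [P(e, 1, "Q8N5Z0", n, "Kynurenine/alpha-aminoadipate aminotransferase, mitochondrial")]
    add("2qlr", 1, kat("2qlr", 4), "kat2_tetramer", symmetry="D2")
    add("2r2n", 1, kat("2r2n", 2), "kat2_dimer", symmetry="C2")
    for i in range(14):
        add(f"{7100 + i:04d}", 1, kat(f"{7100 + i:04d}", 2), "kat2_dimer", symmetry="C2")

    # symmetry-inconsistent histidine-kinase dimers
    group("histidine_kinase", "Sensor histidine kinase", "uniprot", symmetry_consistent=False)
    hk = lambda e: [P(e, 1, "A0A0M3KKX3", 2, "Sensor histidine kinase", tax=562)]
    add("4u7n", 1, hk("4u7n"), "histidine_kinase", symmetry="C2")
    add("4u7o", 1, hk("4u7o"), "histidine_kinase", symmetry="asymmetric")
    add("4zki", 1, hk("4zki"), "histidine_kinase", symmetry="asymmetric")

    # chimeric fusion: excluded from identification
    group("chimera", None, "excluded", excluded=True)
    add("9chi", 1, [P("9chi", 1, None, 1, name="fusion construct",
                      accessions=("P0DTD1", "P68871"))], "chimera")

    # Table-5 label exemplars as single assemblies
    group("label_antibody", "murine antibody Fab fragment", "unnamed")
    add("5mv4", 1, [P("5mv4", 1, None, 1, name="murine antibody Fab fragment", antibody=True, tax=10090)],
        "label_antibody")
    group("label_unmapped_protein", "Cytochrome c, de novo designed binder complex", "uniprot")
    add("7rx0", 1, [
        P("7rx0", 1, "P99999", 1, "Cytochrome c"),
        P("7rx0", 2, None, 1, name="de novo designed binder"),
    ], "label_unmapped_protein")
    group("label_unmapped_rna", "Sex-lethal protein, RNA complex", "uniprot")
    add("1un6", 1, [
        P("1un6", 1, "P19339", 1, "Sex-lethal protein", tax=7227),
        N("1un6", 2, "RNA", 1, name="poly-U RNA", tax=None),
    ], "label_unmapped_rna")
    group("label_dna", None, "unnamed")
    add("8b1t", 1, [
        P("8b1t", 1, "P06746", 1, "DNA polymerase beta"),
        P("8b1t", 2, "P61421", 1, "Accessory subunit"),
        P("8b1t", 3, "P61962", 1, "Second accessory subunit"),
        N("8b1t", 4, "DNA", 1, name="gapped DNA substrate", tax=9606),
    ], "label_dna")
    group("label_hybrid", None, "unnamed")
    add("8e8j", 1, [
        P("8e8j", 1, "P04585", 1, "Reverse transcriptase"),
        P("8e8j", 2, "P04587", 1, "RNase H subunit"),
        N("8e8j", 3, "DNA/RNA", 1, name="RNA/DNA duplex", tax=None),
    ], "label_hybrid")

    # fix truth names for the groups whose antibody/unnamed labels differ
    truth.groups["label_antibody"].name = "murine antibody Fab fragment"
    truth.groups["label_antibody"].category = "antibody"

    return FixtureBundle(assemblies, portal, curated, truth)
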