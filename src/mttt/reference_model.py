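"""Fixed biological reference data.

This module loads and validates everything the pipeline treats as given:
the rCRS segment of the MT-TT gene, the tRNA structural model (mtDNA ->
tRNAdb position map, element labels, Watson-Crick pairing table), the
catalog of known LHON-associated mtDNA mutations, and a curated
haplogroup tree of defining variants.  All of it ships as editable text
files under ``mttt/data`` and can be replaced by user-supplied files of
the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

from .variants import MtVariant, parse_variant


class GeneModelError(ValueError):
    """Malformed or inconsistent gene-model configuration."""


class TreeError(ValueError):
    """Malformed haplogroup tree."""


def _data_path(name: str) -> Path:
    return Path(resources.files("mttt").joinpath("data", name))


@dataclass(frozen=True)
class RcrsSegment:
    """A contiguous rCRS extract, 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise GeneModelError(
                f"segment length {len(self.sequence)} != {self.end}-{self.start}+1"
            )

    def base_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise GeneModelError(f"position {position} outside {self.start}..{self.end}")
        return self.sequence[position - self.start]

    def run_at(self, position: int, length: int) -> str:
        return "".join(self.base_at(position + i) for i in range(length))


@dataclass
class TrnaGeneModel:
    """MT-TT coordinates plus the tRNA structural annotation layers."""

    gene_name: str
    segment: RcrsSegment
    position_map: dict[int, int]  # mtDNA coordinate -> tRNAdb position
    element_map: dict[int, str]  # tRNAdb position -> structural element
    pairing_table: frozenset[frozenset[int]]

    def __post_init__(self) -> None:
        inv: dict[int, int] = {}
        prev = 0
        for coord in sorted(self.position_map):
            db = self.position_map[coord]
            if db <= prev:
                raise GeneModelError(f"position map not strictly increasing at m.{coord}")
            prev = db
            inv[db] = coord
        self.coordinate_map = inv  # tRNAdb position -> mtDNA coordinate
        self._partners: dict[int, int] = {}
        for pair in self.pairing_table:
            a, b = sorted(pair)
            for p in (a, b):
                if p not in self.element_map:
                    raise GeneModelError(f"paired tRNAdb position {p} has no element label")
            self._partners[a] = b
            self._partners[b] = a

    @property
    def trnadb_positions(self) -> list[int]:
        """tRNAdb positions present in the gene, 5' to 3'."""
        return sorted(self.coordinate_map)

    def trnadb_position(self, coordinate: int) -> int:
        if coordinate not in self.position_map:
            raise GeneModelError(f"m.{coordinate} outside {self.gene_name}")
        return self.position_map[coordinate]

    def base_at_trnadb(self, trnadb_pos: int) -> str:
        return self.segment.base_at(self.coordinate_map[trnadb_pos])


def pairing_partner(model: TrnaGeneModel, trnadb_pos: int) -> int | None:
    """Watson-Crick partner of a tRNAdb position, or None for loop sites."""
    if trnadb_pos not in model.element_map:
        raise GeneModelError(f"unknown tRNAdb position {trnadb_pos}")
    return model._partners.get(trnadb_pos)


def _interpolate_position_map(
    anchors: dict[int, int], start: int, end: int
) -> dict[int, int]:
    """Fill the full mtDNA->tRNAdb map from anchor points.

    Each coordinate inherits the offset (tRNAdb minus 1-based segment
    index) of the nearest anchor at or upstream of it; coordinates
    upstream of the first anchor use the first anchor's offset.  Offsets
    may only grow downstream (skipped canonical positions); a shrinking
    offset cannot produce a strictly increasing map and is rejected.
    """
    if not anchors:
        raise GeneModelError("no numbering anchors supplied")
    items = sorted(anchors.items())
    for (mt_a, db_a), (mt_b, db_b) in zip(items, items[1:]):
        if db_b <= db_a:
            raise GeneModelError(
                f"non-monotone anchors: m.{mt_a}->{db_a} then m.{mt_b}->{db_b}"
            )
        if db_b - db_a < mt_b - mt_a:
            raise GeneModelError(
                f"anchors m.{mt_a}->{db_a} and m.{mt_b}->{db_b} leave no room "
                "for a strictly increasing fill"
            )
    offsets = [(mt, db - (mt - start + 1)) for mt, db in items]
    out: dict[int, int] = {}
    for coord in range(start, end + 1):
        off = offsets[0][1]
        for mt, o in offsets:
            if mt <= coord:
                off = o
            else:
                break
        out[coord] = (coord - start + 1) + off
    if out[start] < 1:
        raise GeneModelError("interpolated map starts below tRNAdb position 1")
    return out


def load_gene_model(config_path: str | Path | None = None) -> TrnaGeneModel:
    """Load the tRNA gene model from a YAML config (default: shipped MT-TT)."""
    path = Path(config_path) if config_path else _data_path("gene_model.yaml")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - depends on input
        raise GeneModelError(f"malformed gene model file {path}: {exc}") from exc
    for key in ("gene", "reference", "numbering", "elements", "pairing"):
        if key not in cfg:
            raise GeneModelError(f"gene model file {path} missing section {key!r}")

    ref = cfg["reference"]
    fasta = path.parent / ref["fasta"]
    record = next(SeqIO.parse(str(fasta), "fasta"))
    segment = RcrsSegment(int(ref["start"]), int(ref["end"]), str(record.seq).upper())

    anchors = {int(k): int(v) for k, v in cfg["numbering"]["anchors"].items()}
    for coord in anchors:
        if not segment.start <= coord <= segment.end:
            raise GeneModelError(f"anchor m.{coord} outside the gene segment")
    position_map = _interpolate_position_map(anchors, segment.start, segment.end)
    for coord, db in anchors.items():
        if position_map[coord] != db:  # pragma: no cover - internal consistency
            raise GeneModelError(f"anchor m.{coord}->{db} not honoured by interpolation")

    element_map: dict[int, str] = {}
    for element, ranges in cfg["elements"].items():
        for lo, hi in ranges:
            for p in range(int(lo), int(hi) + 1):
                element_map[p] = element
    for coord, db in position_map.items():
        if db not in element_map:
            raise GeneModelError(f"tRNAdb position {db} (m.{coord}) has no element label")

    pairing = frozenset(frozenset((int(a), int(b))) for a, b in cfg["pairing"])
    return TrnaGeneModel(str(cfg["gene"]), segment, position_map, element_map, pairing)


@dataclass
class KnownMutationCatalog:
    """Reported LHON-associated mtDNA mutations, by category.

    Categories: ``primary`` (the top primary LHON mutations, including
    the three classic screening mutations m.3460G>A, m.11778G>A and
    m.14484T>C), ``candidate`` (other reported candidates) and
    ``known_MT_TT`` (the two established MT-TT mutations).
    """

    entries: dict[str, tuple[str, str, str]]  # label -> (gene, aa_change, category)

    def category(self, variant: MtVariant | str) -> str | None:
        label = variant if isinstance(variant, str) else variant.label
        entry = self.entries.get(label)
        return entry[2] if entry else None

    def labels(self, category: str | None = None) -> set[str]:
        return {
            lab
            for lab, (_, _, cat) in self.entries.items()
            if category is None or cat == category
        }


def load_catalog(path: str | Path | None = None) -> KnownMutationCatalog:
    path = Path(path) if path else _data_path("known_mutations.tsv")
    entries: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "variant", "aa_change", "category"]:
            raise GeneModelError(f"unexpected catalog header in {path}: {header}")
        for line in fh:
            gene, variant, aa, category = line.rstrip("\n").split("\t")
            parse_variant(variant)  # validates the label
            entries[variant] = (gene, aa, category)
    return KnownMutationCatalog(entries)


@dataclass
class HaplogroupNode:
    name: str
    parent: str | None
    defining_variants: list[MtVariant]


@dataclass
class HaplogroupTree:
    """Nested clades, each with the variants defining its branch."""

    root: str
    nodes: dict[str, HaplogroupNode]
    macro_map: dict[str, str] = field(default_factory=dict)  # node -> macro name

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise TreeError(f"root {self.root!r} not among nodes")
        if self.nodes[self.root].parent is not None:
            raise TreeError("root node must have no parent")
        for node in self.nodes.values():
            if node.name == self.root:
                continue
            if node.parent not in self.nodes:
                raise TreeError(f"node {node.name!r} has unknown parent {node.parent!r}")
            self.path(node.name)  # raises on cycles / unreachable

    def path(self, name: str) -> list[HaplogroupNode]:
        """Root -> node chain."""
        if name not in self.nodes:
            raise TreeError(f"unknown haplogroup {name!r}")
        chain: list[HaplogroupNode] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise TreeError(f"cycle in tree at {cur!r}")
            seen.add(cur)
            chain.append(self.nodes[cur])
            cur = self.nodes[cur].parent
        if chain[-1].name != self.root:
            raise TreeError(f"node {name!r} not reachable from root")
        return list(reversed(chain))

    def path_variants(self, name: str) -> list[MtVariant]:
        out: list[MtVariant] = []
        for node in self.path(name):
            out.extend(node.defining_variants)
        return out

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def all_defining_positions(self) -> set[int]:
        out: set[int] = set()
        for node in self.nodes.values():
            for v in node.defining_variants:
                out.update(range(v.position, v.end + 1))
        return out

    def macro(self, name: str) -> str:
        return self.macro_map.get(name, "other")


def load_haplogroup_tree(path: str | Path | None = None) -> HaplogroupTree:
    path = Path(path) if path else _data_path("haplogroup_tree.yaml")
    cfg = yaml.safe_load(path.read_text())
    nodes = {
        str(name): HaplogroupNode(
            str(name),
            None if spec.get("parent") is None else str(spec["parent"]),
            [parse_variant(lab) for lab in spec.get("variants", [])],
        )
        for name, spec in cfg["nodes"].items()
    }
    macro_map = {
        str(node): str(macro)
        for macro, members in cfg.get("macro", {}).items()
        for node in members
    }
    return HaplogroupTree(str(cfg["root"]), nodes, macro_map)
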