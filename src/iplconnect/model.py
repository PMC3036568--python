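"""Circle-annotation data model for serial-section connectome volumes.

A volume is annotated one slice at a time: each neural process is described
by the largest circle that fits inside it on each slice (a :class:`Location`),
and circles on nearby slices are strung together into a 3-D process by
:class:`LocationLink` edges.  Cells own child structures (synapses, ribbons,
gap junctions, cistern contacts, adjacency markers), and child structures of
different cells are joined by :class:`StructureLink` rows — the raw material
for the cell-level circuit graph.

The on-disk interchange format is a directory of plain-text tables::

    volume.json          pixel size, slice thicknesses, slice count, skips
    structures.csv       id,kind,cell_class,parent_id,contact_type,compartment
    locations.csv        id,structure_id,z,center_x,center_y,radius
    location_links.csv   a,b
    structure_links.csv  source,target,directed[,channel]
    signatures.csv       structure_id,channel,pixel_value

All tables are UTF-8 CSV with a mandatory header row; integers are written
bare and floats with a ``.`` decimal.  ``save_annotations`` writes a canonical
(sorted) form so that save -> load -> save is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "CONTACT_TYPES",
    "DIRECTED_CONTACT_TYPES",
    "UNDIRECTED_CONTACT_TYPES",
    "SIGNATURE_CHANNELS",
    "COMPARTMENTS",
    "ValidationError",
    "VolumeMeta",
    "MolecularSignature",
    "Structure",
    "Location",
    "LocationLink",
    "StructureLink",
    "AnnotationModel",
    "load_annotations",
    "save_annotations",
    "physical_position",
    "arbor_diameter",
    "contact_census",
]

# Contact ontology.  Synaptic contacts (chemical synapses, ribbons, cistern
# contacts) are directed pre -> post; gap junctions and bare membrane
# appositions ("adjacency") are symmetric.
DIRECTED_CONTACT_TYPES = ("conventional_synapse", "ribbon_synapse", "cistern_contact")
UNDIRECTED_CONTACT_TYPES = ("gap_junction", "adjacency")
CONTACT_TYPES = DIRECTED_CONTACT_TYPES + UNDIRECTED_CONTACT_TYPES

SIGNATURE_CHANNELS = ("GABA", "glycine", "glutamate", "taurine", "glutamine", "AGB")
COMPARTMENTS = ("soma", "dendrite", "axon", "terminal", "unknown")

#: Default slice-to-slice link reach, in slices.  Serial-section volumes lose
#: occasional sections (film failures, refacing); links may bridge up to this
#: many slices so processes survive a short run of missing sections.
DEFAULT_MAX_GAP = 6


class ValidationError(ValueError):
    """Raised when interchange tables violate a model invariant.

    ``rows`` lists the offending entities (table name, identifying values).
    """

    def __init__(self, message: str, rows: Sequence[tuple] = ()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message}: {self.rows}"
        super().__init__(message)


@dataclass(frozen=True)
class VolumeMeta:
    """Coordinate frame of a volume.

    Parameters
    ----------
    pixel_size_nm:
        Lateral sampling, nm per pixel (TEM mosaics here are 2.18 nm/px).
    slice_thickness_nm:
        Either a single nominal thickness or a per-slice sequence, nm.
        Serial sections are typically cut at 70-90 nm.
    slice_count:
        Number of slice planes (including skipped ones).
    skipped_slices:
        Slice indices with no usable image; they still occupy physical depth.
    volume_diameter_um:
        Optional diameter of the captured field, micrometres.
    """

    pixel_size_nm: float = 2.18
    slice_thickness_nm: float | Sequence[float] = 70.0
    slice_count: int = 1
    skipped_slices: frozenset[int] = frozenset()
    volume_diameter_um: float | None = None

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be > 0")
        object.__setattr__(self, "skipped_slices", frozenset(self.skipped_slices))
        t = self.thickness_table()
        if len(t) != self.slice_count:
            raise ValidationError(
                f"need {self.slice_count} slice thicknesses, got {len(t)}"
            )
        if np.any(t <= 0):
            raise ValidationError("every slice thickness must be > 0")
        bad = [z for z in self.skipped_slices if not (0 <= z < self.slice_count)]
        if bad:
            raise ValidationError("skipped slice outside volume", [("volume", z) for z in bad])

    def thickness_table(self) -> np.ndarray:
        """Per-slice thickness in nm, shape ``(slice_count,)``."""
        if np.isscalar(self.slice_thickness_nm):
            return np.full(self.slice_count, float(self.slice_thickness_nm))
        return np.asarray(self.slice_thickness_nm, dtype=float)

    def z_offsets_nm(self) -> np.ndarray:
        """Cumulative depth of the *top* of each slice, nm."""
        t = self.thickness_table()
        return np.concatenate([[0.0], np.cumsum(t)[:-1]])


@dataclass(frozen=True)
class MolecularSignature:
    """Mean 8-bit immunosignal pixel values per molecular channel."""

    channels: Mapping[str, float]

    def __post_init__(self):
        bad = [(c, v) for c, v in self.channels.items() if not (0 <= v <= 255)]
        if bad:
            raise ValidationError("signature pixel values must be in [0, 255]", bad)
        object.__setattr__(self, "channels", dict(self.channels))

    def __getitem__(self, channel: str) -> float:
        return self.channels[channel]


@dataclass
class Structure:
    """A cell, or a contact element (synapse, ribbon, ...) owned by a cell."""

    id: int
    kind: str  # "cell" | "child"
    cell_class: str = ""
    parent_id: int | None = None
    contact_type: str | None = None
    compartment: str = "unknown"
    signature: MolecularSignature | None = None

    def __post_init__(self):
        if self.kind not in ("cell", "child"):
            raise ValidationError(f"structure {self.id}: bad kind {self.kind!r}")
        if self.kind == "cell":
            if self.parent_id is not None:
                raise ValidationError(f"cell {self.id} must not have a parent")
            if self.contact_type is not None:
                raise ValidationError(f"cell {self.id} must not have a contact_type")
        else:
            if self.parent_id is None:
                raise ValidationError(f"child {self.id} needs a parent cell")
            if self.contact_type not in CONTACT_TYPES:
                raise ValidationError(
                    f"child {self.id}: bad contact_type {self.contact_type!r}"
                )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"structure {self.id}: bad compartment {self.compartment!r}")


@dataclass(frozen=True)
class Location:
    """A per-slice circle: the largest circle fitting inside a process."""

    id: int
    structure_id: int
    z: int
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError(f"location {self.id}: radius must be > 0")


@dataclass(frozen=True)
class LocationLink:
    """Adjacency between circles of one structure on nearby slices."""

    a: int
    b: int


@dataclass(frozen=True)
class StructureLink:
    """A contact between two child structures of different cells.

    Directed links run presynaptic ``source`` -> postsynaptic ``target``;
    gap junctions and adjacency markers are undirected.  ``channel`` may name
    the transmitter for co-release cases (e.g. dopamine vs glutamate).
    """

    source: int
    target: int
    directed: bool
    channel: str = ""


@dataclass
class AnnotationModel:
    """Validated in-memory annotation set for one volume."""

    meta: VolumeMeta
    structures: dict[int, Structure] = field(default_factory=dict)
    locations: dict[int, Location] = field(default_factory=dict)
    location_links: list[LocationLink] = field(default_factory=list)
    structure_links: list[StructureLink] = field(default_factory=list)
    max_gap: int = DEFAULT_MAX_GAP

    # -- convenience accessors -------------------------------------------

    def cells(self) -> list[Structure]:
        return [s for s in self.structures.values() if s.kind == "cell"]

    def children_of(self, cell_id: int) -> list[Structure]:
        return [
            s
            for s in self.structures.values()
            if s.kind == "child" and s.parent_id == cell_id
        ]

    def parent_cell(self, child_id: int) -> Structure:
        child = self.structures[child_id]
        if child.kind == "cell":
            return child
        return self.structures[child.parent_id]

    def locations_of(self, structure_id: int) -> list[Location]:
        return [l for l in self.locations.values() if l.structure_id == structure_id]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check every model invariant; raise :class:`ValidationError` on the
        first violated class of invariant, listing all offending rows."""
        meta = self.meta
        bad = []
        for s in self.structures.values():
            if s.kind == "child" and s.parent_id not in self.structures:
                bad.append(("structures", s.id, "dangling parent", s.parent_id))
            elif s.kind == "child" and self.structures[s.parent_id].kind != "cell":
                bad.append(("structures", s.id, "parent is not a cell", s.parent_id))
        if bad:
            raise ValidationError("invalid parent references", bad)

        for l in self.locations.values():
            if l.structure_id not in self.structures:
                bad.append(("locations", l.id, "dangling structure", l.structure_id))
            if not (0 <= l.z < meta.slice_count):
                bad.append(("locations", l.id, "z outside volume", l.z))
            elif l.z in meta.skipped_slices:
                bad.append(("locations", l.id, "z on skipped slice", l.z))
        if bad:
            raise ValidationError("invalid locations", bad)

        seen = set()
        for ll in self.location_links:
            key = (min(ll.a, ll.b), max(ll.a, ll.b))
            if key in seen:
                bad.append(("location_links", ll.a, ll.b, "duplicate link"))
                continue
            seen.add(key)
            if ll.a not in self.locations or ll.b not in self.locations:
                bad.append(("location_links", ll.a, ll.b, "dangling location"))
                continue
            la, lb = self.locations[ll.a], self.locations[ll.b]
            if la.structure_id != lb.structure_id:
                bad.append(("location_links", ll.a, ll.b, "links two structures"))
            if la.z == lb.z:
                bad.append(("location_links", ll.a, ll.b, "same slice"))
            elif abs(la.z - lb.z) > self.max_gap:
                bad.append(("location_links", ll.a, ll.b, f"gap > {self.max_gap}"))
        if bad:
            raise ValidationError("invalid location links", bad)

        seen = set()
        for sl in self.structure_links:
            key = (sl.source, sl.target, sl.directed, sl.channel)
            ukey = (min(sl.source, sl.target), max(sl.source, sl.target), sl.directed, sl.channel)
            if (key if sl.directed else ukey) in seen:
                bad.append(("structure_links", sl.source, sl.target, "duplicate link"))
                continue
            seen.add(key if sl.directed else ukey)
            for end in (sl.source, sl.target):
                if end not in self.structures:
                    bad.append(("structure_links", sl.source, sl.target, "dangling endpoint", end))
                elif self.structures[end].kind != "child":
                    bad.append(("structure_links", sl.source, sl.target, "endpoint not a child", end))
            if sl.source in self.structures and sl.target in self.structures:
                src, tgt = self.structures[sl.source], self.structures[sl.target]
                if src.kind == "child" and tgt.kind == "child":
                    ct = src.contact_type
                    if ct in UNDIRECTED_CONTACT_TYPES and sl.directed:
                        bad.append(("structure_links", sl.source, sl.target, f"{ct} must be undirected"))
                    if ct in DIRECTED_CONTACT_TYPES and not sl.directed:
                        bad.append(("structure_links", sl.source, sl.target, f"{ct} must be directed"))
        if bad:
            raise ValidationError("invalid structure links", bad)


# -- interchange I/O ------------------------------------------------------

_TABLES = ("structures", "locations", "location_links", "structure_links", "signatures")


def _fmt_float(x: float) -> str:
    """Bare integers for integral values, '.' decimal otherwise."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def save_annotations(model: AnnotationModel, directory: str | Path) -> None:
    """Write the model as the canonical interchange directory.

    Rows are sorted by id so the output is a deterministic function of the
    model contents.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = model.meta

    thick = meta.slice_thickness_nm
    if not np.isscalar(thick):
        thick = [float(t) for t in thick]
    else:
        thick = float(thick)
    vol = {
        "pixel_size_nm": float(meta.pixel_size_nm),
        "slice_thickness_nm": thick,
        "slice_count": int(meta.slice_count),
        "skipped_slices": sorted(int(z) for z in meta.skipped_slices),
    }
    if meta.volume_diameter_um is not None:
        vol["volume_diameter_um"] = float(meta.volume_diameter_um)
    (directory / "volume.json").write_text(json.dumps(vol, indent=1) + "\n")

    rows = []
    for s in sorted(model.structures.values(), key=lambda s: s.id):
        rows.append(
            [
                s.id,
                s.kind,
                s.cell_class,
                "" if s.parent_id is None else s.parent_id,
                s.contact_type or "",
                s.compartment,
            ]
        )
    _write_csv(
        directory / "structures.csv",
        ["id", "kind", "cell_class", "parent_id", "contact_type", "compartment"],
        rows,
    )

    rows = [
        [l.id, l.structure_id, l.z, _fmt_float(l.center_x), _fmt_float(l.center_y), _fmt_float(l.radius)]
        for l in sorted(model.locations.values(), key=lambda l: l.id)
    ]
    _write_csv(
        directory / "locations.csv",
        ["id", "structure_id", "z", "center_x", "center_y", "radius"],
        rows,
    )

    rows = sorted([min(l.a, l.b), max(l.a, l.b)] for l in model.location_links)
    _write_csv(directory / "location_links.csv", ["a", "b"], rows)

    rows = sorted(
        [l.source, l.target, int(l.directed), l.channel] for l in model.structure_links
    )
    _write_csv(
        directory / "structure_links.csv", ["source", "target", "directed", "channel"], rows
    )

    rows = []
    for s in sorted(model.structures.values(), key=lambda s: s.id):
        if s.signature is not None:
            for ch in sorted(s.signature.channels):
                rows.append([s.id, ch, _fmt_float(s.signature.channels[ch])])
    _write_csv(directory / "signatures.csv", ["structure_id", "channel", "pixel_value"], rows)


def _write_csv(path: Path, header: list[str], rows: Iterable[Sequence]) -> None:
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_annotations(directory: str | Path, max_gap: int = DEFAULT_MAX_GAP) -> AnnotationModel:
    """Read and fully validate an interchange directory.

    Raises
    ------
    ValidationError
        On schema violations, dangling references, duplicate links, or
        locations on skipped / nonexistent slices; the error lists the
        offending rows.
    """
    directory = Path(directory)
    try:
        vol = json.loads((directory / "volume.json").read_text())
    except FileNotFoundError:
        raise ValidationError(f"missing volume.json in {directory}")
    meta = VolumeMeta(
        pixel_size_nm=vol["pixel_size_nm"],
        slice_thickness_nm=vol["slice_thickness_nm"],
        slice_count=vol["slice_count"],
        skipped_slices=frozenset(vol.get("skipped_slices", ())),
        volume_diameter_um=vol.get("volume_diameter_um"),
    )

    def read(name: str, required_cols: list[str]) -> pd.DataFrame:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise ValidationError(f"missing table {name}.csv")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        missing = [c for c in required_cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name}.csv missing columns", [(name, c) for c in missing])
        return df

    model = AnnotationModel(meta=meta, max_gap=max_gap)

    sdf = read("structures", ["id", "kind", "cell_class", "parent_id", "contact_type", "compartment"])
    for row in sdf.itertuples(index=False):
        sid = int(row.id)
        if sid in model.structures:
            raise ValidationError("duplicate structure id", [("structures", sid)])
        model.structures[sid] = Structure(
            id=sid,
            kind=row.kind,
            cell_class=row.cell_class,
            parent_id=None if row.parent_id == "" else int(row.parent_id),
            contact_type=None if row.contact_type == "" else row.contact_type,
            compartment=row.compartment or "unknown",
        )

    gdf = read("signatures", ["structure_id", "channel", "pixel_value"])
    sig: dict[int, dict[str, float]] = {}
    for row in gdf.itertuples(index=False):
        sig.setdefault(int(row.structure_id), {})[row.channel] = float(row.pixel_value)
    for sid, channels in sig.items():
        if sid not in model.structures:
            raise ValidationError("signature for unknown structure", [("signatures", sid)])
        model.structures[sid].signature = MolecularSignature(channels)

    ldf = read("locations", ["id", "structure_id", "z", "center_x", "center_y", "radius"])
    for row in ldf.itertuples(index=False):
        lid = int(row.id)
        if lid in model.locations:
            raise ValidationError("duplicate location id", [("locations", lid)])
        model.locations[lid] = Location(
            id=lid,
            structure_id=int(row.structure_id),
            z=int(row.z),
            center_x=float(row.center_x),
            center_y=float(row.center_y),
            radius=float(row.radius),
        )

    lldf = read("location_links", ["a", "b"])
    for row in lldf.itertuples(index=False):
        model.location_links.append(LocationLink(a=int(row.a), b=int(row.b)))

    sldf = read("structure_links", ["source", "target", "directed"])
    has_channel = "channel" in sldf.columns
    for row in sldf.itertuples(index=False):
        model.structure_links.append(
            StructureLink(
                source=int(row.source),
                target=int(row.target),
                directed=bool(int(row.directed)),
                channel=row.channel if has_channel else "",
            )
        )

    model.validate()
    return model


# -- geometric / census summaries -----------------------------------------


def physical_position(loc: Location, meta: VolumeMeta) -> tuple[float, float, float]:
    """Physical (x, y, z) of a circle centre in nm.

    x and y scale by the pixel size; z is the cumulative thickness of all
    slices above the location's slice (skipped slices still occupy depth).
    """
    z_nm = float(meta.z_offsets_nm()[loc.z])
    return (loc.center_x * meta.pixel_size_nm, loc.center_y * meta.pixel_size_nm, z_nm)


def arbor_diameter(model: AnnotationModel, cell_id: int) -> float:
    """Maximal arboreal diameter of a cell in micrometres.

    Defined as the maximum pairwise XY (in-plane) distance between the
    centres of the cell's annotation circles, over the cell and all its
    children; circle radii are not added.
    """
    sids = {cell_id} | {c.id for c in model.children_of(cell_id)}
    pts = np.array(
        [
            (l.center_x, l.center_y)
            for l in model.locations.values()
            if l.structure_id in sids
        ],
        dtype=float,
    )
    if pts.size == 0:
        raise ValueError(f"cell {cell_id} has no locations")
    if len(pts) == 1:
        return 0.0
    d_px = float(pdist(pts).max())
    return d_px * model.meta.pixel_size_nm / 1000.0


def contact_census(model: AnnotationModel, cell_id: int) -> dict[str, int]:
    """Count contact sites of a cell by role.

    Returns a dict with keys ``postsynaptic`` (directed links targeting the
    cell's children), ``presynaptic`` (directed links sourced from them),
    ``gap_junction`` and ``adjacency`` (undirected, once per link), and
    ``cistern`` (cistern-contact links touching the cell, in either role;
    these are also included in the pre/postsynaptic totals).
    """
    if cell_id not in model.structures:
        raise KeyError(cell_id)
    mine = {c.id for c in model.children_of(cell_id)}
    counts = {"postsynaptic": 0, "presynaptic": 0, "gap_junction": 0, "cistern": 0, "adjacency": 0}
    for link in model.structure_links:
        src_in = link.source in mine
        tgt_in = link.target in mine
        if not (src_in or tgt_in):
            continue
        ct = model.structures[link.source].contact_type
        if link.directed:
            if tgt_in:
                counts["postsynaptic"] += 1
            if src_in:
                counts["presynaptic"] += 1
            if ct == "cistern_contact":
                counts["cistern"] += 1
        else:
            counts["gap_junction" if ct == "gap_junction" else "adjacency"] += 1
    return counts
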