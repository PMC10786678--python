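"""Reading and writing coarse-grained protein-shell structures.

A protein shell is reduced to one site per amino acid, placed on the
alpha-carbon (CA).  Only ``ATOM`` records of amino-acid polymers
contribute; HETATM records, nucleic acids, ligands and waters are
excluded.  Alternate locations are resolved to the highest-occupancy
copy.  Multi-model files contribute only their first model.

The residue order is deterministic: chains in file order, then author
residue number, then insertion code.  Internal indexing is positional
and 0-based; author numbering is carried only for reporting.
"""

from __future__ import annotations

import io
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Structure",
    "StructureError",
    "ParseError",
    "EmptyStructureError",
    "parse_structure",
    "parse_structure_file",
    "fetch_structure",
    "write_annotated_structure",
    "write_labels_csv",
]

#: default remote endpoint for mmCIF retrieval (public structure archive)
DEFAULT_URL_TEMPLATE = "https://files.rcsb.org/download/{pdb_id}.cif"

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class StructureError(Exception):
    """Base class for structure I/O failures."""


class ParseError(StructureError):
    """The input text is not well-formed in the named format."""


class EmptyStructureError(StructureError):
    """No amino-acid alpha-carbon was found in the input."""


@dataclass(frozen=True)
class Residue:
    """One coarse-grained site: the CA atom of an amino acid.

    Attributes
    ----------
    chain_id : str
        Author chain identifier.
    residue_number : int
        Author residue number.
    insertion_code : str
        PDB insertion code, ``""`` when absent.
    residue_name : str
        Three-letter residue code.
    coord : numpy.ndarray
        CA position, Å, shape ``(3,)``.
    bfactor : float
        Experimental temperature factor, Å²; ``nan`` when missing.
    """

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    coord: np.ndarray
    bfactor: float

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"invalid coordinate {self.coord!r}")
        object.__setattr__(self, "coord", coord)


@dataclass
class Structure:
    """An ordered list of coarse-grained residues."""

    residues: list[Residue]
    source_id: str = ""
    title: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of CA coordinates in Å."""
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        """(N,) array of experimental B-factors in Å²."""
        return np.array([r.bfactor for r in self.residues], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        return [r.chain_id for r in self.residues]


def _atoms_to_structure(atoms: struc.AtomArray, source_id: str, title: str) -> Structure:
    """Reduce a biotite AtomArray to one CA site per amino acid."""
    mask = (
        struc.filter_amino_acids(atoms)
        & (atoms.atom_name == "CA")
        & ~atoms.hetero
    )
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise EmptyStructureError(
            f"no amino-acid alpha-carbon atoms found in {source_id or 'input'}"
        )

    chain_ids = atoms.chain_id
    # chains keep file order; residues sort by author number then icode
    order_of_chain = {c: i for i, c in enumerate(dict.fromkeys(chain_ids))}
    chain_rank = np.array([order_of_chain[c] for c in chain_ids])
    ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else np.full(
        atoms.array_length(), "", dtype="U1"
    )
    order = np.lexsort((ins, atoms.res_id, chain_rank))
    atoms = atoms[order]
    ins = ins[order]

    bfac = (
        atoms.b_factor
        if "b_factor" in atoms.get_annotation_categories()
        else np.full(atoms.array_length(), np.nan)
    )

    residues: list[Residue] = []
    seen: set[tuple[str, int, str]] = set()
    for k in range(atoms.array_length()):
        key = (str(atoms.chain_id[k]), int(atoms.res_id[k]), str(ins[k]))
        if key in seen:
            logger.warning("duplicate CA for residue %s; keeping first", key)
            continue
        seen.add(key)
        residues.append(
            Residue(
                chain_id=key[0],
                residue_number=key[1],
                insertion_code=key[2],
                residue_name=str(atoms.res_name[k]),
                coord=atoms.coord[k].astype(float),
                bfactor=float(bfac[k]),
            )
        )
    return Structure(residues=residues, source_id=source_id, title=title)


def parse_structure(text: str, format: str = "pdb", source_id: str = "") -> Structure:
    """Parse PDB or PDBx/mmCIF text into a coarse-grained :class:`Structure`.

    Parameters
    ----------
    text : str
        Full file content.
    format : {"pdb", "mmcif"}
    source_id : str, optional
        Identifier recorded on the result (file name or database code).

    Returns
    -------
    Structure
        One residue per amino acid carrying a CA ``ATOM`` record, with
        that atom's coordinates and B-factor.

    Raises
    ------
    ParseError
        Malformed input.
    EmptyStructureError
        No amino-acid CA atoms present.
    """
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    fields = ["b_factor", "occupancy"]
    title = ""
    try:
        if format == "pdb":
            pf = pdbio.PDBFile.read(io.StringIO(text))
            n_models = pf.get_model_count()
            if n_models > 1:
                logger.info("file has %d models; reading the first only", n_models)
            atoms = pdbio.get_structure(
                pf, model=1, extra_fields=fields, altloc="occupancy"
            )
        else:
            cf = pdbxio.CIFFile.read(io.StringIO(text))
            atoms = pdbxio.get_structure(
                cf, model=1, extra_fields=fields, altloc="occupancy"
            )
    except Exception as exc:  # biotite raises format-specific errors
        raise ParseError(f"cannot parse {format} input: {exc}") from exc
    return _atoms_to_structure(atoms, source_id=source_id, title=title)


def parse_structure_file(path: str | Path) -> Structure:
    """Parse a structure file, inferring the format from its suffix."""
    path = Path(path)
    fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    return parse_structure(path.read_text(), format=fmt, source_id=path.name)


def fetch_structure(
    identifier: str,
    cache_dir: str | Path = ".",
    url_template: str = DEFAULT_URL_TEMPLATE,
    _opener=urllib.request.urlopen,
) -> Structure:
    """Retrieve an mmCIF entry by 4-character database code, with caching.

    A previously downloaded file in ``cache_dir`` is reused without any
    network access.
    """
    identifier = identifier.strip()
    if not _PDB_ID_RE.match(identifier):
        raise ValueError(
            f"{identifier!r} is not a valid 4-character structure identifier"
        )
    identifier = identifier.lower()
    cache_dir = Path(cache_dir)
    cached = cache_dir / f"{identifier}.cif"
    if cached.exists():
        logger.info("using cached %s", cached)
        return parse_structure(cached.read_text(), "mmcif", source_id=identifier)

    url = url_template.format(pdb_id=identifier)
    try:
        with _opener(url) as resp:
            text = resp.read().decode()
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise StructureError(f"identifier {identifier!r} not found at archive") from exc
        raise StructureError(f"download failed for {identifier!r}: {exc}") from exc
    except urllib.error.URLError as exc:
        raise StructureError(
            f"no network access ({exc.reason}); supply a local PDB/mmCIF file instead"
        ) from exc
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    return parse_structure(text, "mmcif", source_id=identifier)


def _to_atom_array(structure: Structure, bvalues: np.ndarray) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([r.chain_id for r in structure.residues])
    arr.res_id = np.array([r.residue_number for r in structure.residues])
    arr.ins_code = np.array([r.insertion_code for r in structure.residues])
    arr.res_name = np.array([r.residue_name for r in structure.residues])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("b_factor", np.asarray(bvalues, dtype=float))
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def write_annotated_structure(structure: Structure, labels, out_format: str = "pdb") -> str:
    """Emit a CA-only PDB with cluster labels in the B-factor column.

    Re-parsing the output recovers coordinates to format precision and the
    labels exactly (as integers).
    """
    if out_format != "pdb":
        raise ValueError(f"unsupported output format {out_format!r}")
    labels = np.asarray(labels)
    if labels.shape != (len(structure),):
        raise ValueError(
            f"labels length {labels.shape} does not match residue count {len(structure)}"
        )
    if np.any(labels < 0) or np.any(labels > 999):
        raise ValueError("labels must be in [0, 999] to fit the B-factor column")
    arr = _to_atom_array(structure, labels.astype(float))
    pf = pdbio.PDBFile()
    pdbio.set_structure(pf, arr)
    buf = io.StringIO()
    pf.write(buf)
    return buf.getvalue()


def structure_to_pdb(structure: Structure, b_factors=None) -> str:
    """Serialize a Structure as minimal CA-only PDB text (B-factors in Å²)."""
    b = structure.bfactors if b_factors is None else np.asarray(b_factors, float)
    if b.shape != (len(structure),):
        raise ValueError("b_factors length does not match residue count")
    arr = _to_atom_array(structure, b)
    pf = pdbio.PDBFile()
    pdbio.set_structure(pf, arr)
    buf = io.StringIO()
    pf.write(buf)
    return buf.getvalue()


def write_labels_csv(structure: Structure, labels) -> str:
    """Per-residue cluster assignment as CSV text."""
    labels = np.asarray(labels)
    if labels.shape != (len(structure),):
        raise ValueError("labels length does not match residue count")
    lines = ["chain,residue_number,insertion_code,label"]
    for r, lab in zip(structure.residues, labels):
        lines.append(f"{r.chain_id},{r.residue_number},{r.insertion_code},{int(lab)}")
    return "\n".join(lines) + "\n"
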