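"""Readers and writers for the standard formats the toolkit touches.

FASTA (via Biopython), a coarse-grained PDB dialect carrying the three-atom
nucleotide representation (via biotite), dot-bracket secondary structure,
whitespace-delimited contact matrices, ranked-contact and metric TSV
reports, and a compressed distogram archive (no standard format exists for
binned distance maps, so an ``npz`` with a JSON manifest is used).

Conventions: residue and pair indices are 1-based in every external file
(PDB, TSV, dot-bracket) and 0-based in memory; this module converts exactly
once at the boundary.  All writers are deterministic byte-for-byte given
fixed inputs (stable ordering, fixed float formatting).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .cj_contacts import ContactMap, ranked_contacts
from .csor import Decoy, DecoyPool, EnergyBreakdown
from .errors import IngestError
from .geometry import CoarseStructure
from .metrics import BasePairSet
from .networks import Distogram, PairErrorMap
from .rclm import RnaSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_coarse_pdb",
    "write_coarse_pdb",
    "read_dotbracket",
    "write_dotbracket",
    "write_contact_map",
    "read_contact_map",
    "write_ranked_contacts",
    "read_annotations",
    "write_metric_report",
    "write_distogram_archive",
    "read_distogram_archive",
    "write_decoy_pool",
    "read_decoy_pool",
    "write_energies",
]

PURINES = {"A", "G"}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a (multi-record) FASTA file into :class:`RnaSequence` records.

    Lowercase is accepted and T is normalized to U (with a notice).
    """
    path = Path(path)
    records = []
    had_t = False
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        had_t = had_t or ("T" in raw)
        try:
            records.append(RnaSequence(raw, id=rec.id))
        except IngestError as exc:
            raise IngestError(f"{path}: record {rec.id!r}: {exc}") from exc
    if had_t:
        warnings.warn(f"{path}: DNA-style T normalized to U on ingest")
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(seqs):
        if not isinstance(s, RnaSequence):
            s = RnaSequence(s)
        records.append(SeqRecord(Seq(s.symbols), id=s.id or f"seq{i:05d}", description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# coarse PDB
# ---------------------------------------------------------------------------

def _glycosidic_name(residue: str) -> str:
    return "N9" if residue in PURINES else "N1"


def write_coarse_pdb(s: CoarseStructure, path) -> None:
    """Write the three-atom representation as standard ATOM records.

    The glycosidic nitrogen is written as N9 for purines and N1 for
    pyrimidines (defaulting to N1 when no sequence is attached).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    L = len(s)
    seq = s.sequence or "U" * L
    n_atoms = 3 * L
    arr = bst.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    for i in range(L):
        res = seq[i]
        names = ("P", "C4'", _glycosidic_name(res))
        for k in range(3):
            a = 3 * i + k
            arr.chain_id[a] = "A"
            arr.res_id[a] = i + 1
            arr.res_name[a] = res
            arr.atom_name[a] = names[k]
            arr.element[a] = names[k][0]
            arr.hetero[a] = False
            coords[a] = s.coords[i, k]
    arr.coord = coords
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_coarse_pdb(path, chain: str | None = None) -> CoarseStructure:
    """Extract the (P, C4', N1/N9) atom subset from a PDB file.

    Single chain expected; pass ``chain`` to select one from a multi-chain
    file.  Missing required atoms raise with the offending residue numbers.
    """
    path = Path(path)
    arr = PDBFile.read(str(path)).get_structure(model=1)
    chains = sorted(set(arr.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise IngestError(
                f"{path}: multiple chains {chains}; select one with the chain argument")
        chain = chains[0]
    arr = arr[arr.chain_id == chain]
    res_ids = sorted(set(int(r) for r in arr.res_id))
    coords = np.zeros((len(res_ids), 3, 3))
    seq_chars = []
    missing = []
    for idx, rid in enumerate(res_ids):
        sel = arr[arr.res_id == rid]
        res_name = str(sel.res_name[0]).strip()
        base = res_name[-1] if res_name else "U"
        seq_chars.append(base if base in "ACGU" else "U")
        wanted = {"P": 0, "C4'": 1, _glycosidic_name(base): 2}
        found = set()
        for a in range(len(sel)):
            name = str(sel.atom_name[a]).strip()
            if name in wanted:
                coords[idx, wanted[name]] = sel.coord[a]
                found.add(name)
        if len(found) != 3:
            missing.append((rid, sorted(set(wanted) - found)))
    if missing:
        detail = "; ".join(f"residue {rid}: missing {m}" for rid, m in missing[:10])
        raise IngestError(f"{path}: incomplete coarse representation ({detail})")
    sequence = "".join(seq_chars)
    return CoarseStructure(coords, sequence if set(sequence) <= set("ACGU") else None)


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------

def write_dotbracket(length: int, pairs, path, sequence: str | None = None) -> None:
    chars = ["."] * length
    for i, j in pairs:
        i, j = (i, j) if i < j else (j, i)
        chars[i] = "("
        chars[j] = ")"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if sequence:
            fh.write(sequence + "\n")
        fh.write("".join(chars) + "\n")


def read_dotbracket(path):
    """Returns (sequence or None, list of 0-based pairs)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise IngestError(f"{path}: empty dot-bracket file")
    if len(lines) == 1:
        seq, struct = None, lines[0]
    else:
        seq, struct = lines[0], lines[1]
    stack, pairs = [], []
    for idx, ch in enumerate(struct):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise IngestError(f"{path}: unbalanced bracket at column {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise IngestError(f"{path}: unsupported character {ch!r} at column {idx + 1}")
    if stack:
        raise IngestError(f"{path}: {len(stack)} unclosed brackets")
    return seq, sorted(pairs)


# ---------------------------------------------------------------------------
# contact maps / reports
# ---------------------------------------------------------------------------

def write_contact_map(c: ContactMap, path) -> None:
    """L×L whitespace-delimited matrix with the meta flags in a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# corrected={c.meta.get('corrected', False)} "
                 f"symmetrized={c.meta.get('symmetrized', False)} "
                 f"min_separation={c.meta.get('min_separation', 4)}\n")
        for row in c.values:
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")


def read_contact_map(path) -> ContactMap:
    lines = Path(path).read_text().splitlines()
    meta = {"corrected": False, "symmetrized": False, "min_separation": 4}
    rows = []
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                key, _, val = tok.partition("=")
                if key in ("corrected", "symmetrized"):
                    meta[key] = val == "True"
                elif key == "min_separation":
                    meta[key] = int(val)
        elif ln.strip():
            rows.append([float(v) for v in ln.split()])
    return ContactMap(np.array(rows), meta)


def write_ranked_contacts(c: ContactMap, path, max_pairs: int | None = None) -> None:
    """Three-column TSV (i, j, score) of ranked eligible pairs, 1-based."""
    ii, jj, scores = ranked_contacts(c)
    if max_pairs is not None:
        ii, jj, scores = ii[:max_pairs], jj[:max_pairs], scores[:max_pairs]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for a, b, s in zip(ii, jj, scores):
            fh.write(f"{a + 1}\t{b + 1}\t{s:.6e}\n")


def read_annotations(path, length: int | None = None) -> dict:
    """Read a 3-column TSV (i, j, category) of 1-based pair annotations into
    one :class:`BasePairSet` per category plus the union under ``"any"``."""
    by_cat = {"wc": set(), "nwc": set(), "stack": set()}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("i\t"):
            continue
        parts = ln.split()
        if len(parts) != 3 or parts[2] not in by_cat:
            raise IngestError(f"{path}:{lineno}: expected 'i j category(wc|nwc|stack)'")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        by_cat[parts[2]].add((i, j))
    out = {cat: BasePairSet(frozenset(p), cat, length) for cat, p in by_cat.items()}
    out["any"] = BasePairSet(frozenset().union(*by_cat.values()), "any", length)
    return out


def write_metric_report(rows: list, path) -> None:
    """TSV metric report; ``rows`` are dicts with a ``model`` key and metric
    values (missing metrics rendered as NA)."""
    columns = ["model", "tm_score", "rmsd", "inf_wc", "inf_nwc", "inf_stack",
               "inf_all", "di"]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                v = row.get(col)
                if v is None:
                    cells.append("NA")
                elif isinstance(v, str):
                    cells.append(v)
                else:
                    cells.append(f"{v:.4f}")
            fh.write("\t".join(cells) + "\n")


def write_energies(models, path) -> None:
    """energies.tsv for ranked models (model, E_e2e, E_dist, E_total)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("model\tE_e2e\tE_dist\tE_total\n")
        for i, m in enumerate(models, start=1):
            e = m.energy if hasattr(m, "energy") else m
            fh.write(f"model_{i}\t{e.e2e:.4f}\t{e.dist:.4f}\t{e.total:.4f}\n")


# ---------------------------------------------------------------------------
# distogram archives and decoy pools
# ---------------------------------------------------------------------------

def write_distogram_archive(dist: Distogram, path,
                            error_map: PairErrorMap | None = None) -> None:
    manifest = {"format": 1, "length": int(dist.length),
                "channels": ["P-P", "C4'-C4'", "N-N"], "n_bins": 40,
                "has_error_map": error_map is not None}
    payload = {"__manifest__": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
               "probs": dist.probs.astype(np.float32)}
    if error_map is not None:
        payload["error_map"] = error_map.weights.astype(np.float32)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **payload)


def read_distogram_archive(path):
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["__manifest__"]).decode())
        dist = Distogram(archive["probs"].astype(float))
        err = PairErrorMap(archive["error_map"].astype(float)) \
            if manifest.get("has_error_map") else None
    return dist, err


def write_decoy_pool(pool: DecoyPool, out_dir) -> None:
    """A decoy pool as a directory of PDB files + per-decoy distogram archives."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, d in enumerate(pool):
        write_coarse_pdb(d.structure, out_dir / f"decoy_{k:03d}.pdb")
        if d.distogram is not None:
            write_distogram_archive(d.distogram, out_dir / f"decoy_{k:03d}_dist.npz",
                                    d.error_map)


def read_decoy_pool(pool_dir) -> DecoyPool:
    pool_dir = Path(pool_dir)
    pdbs = sorted(pool_dir.glob("decoy_*.pdb"))
    if not pdbs:
        raise IngestError(f"{pool_dir}: no decoy_*.pdb files found")
    decoys = []
    for pdb in pdbs:
        structure = read_coarse_pdb(pdb)
        dist_path = pdb.with_name(pdb.stem + "_dist.npz")
        dist, err = read_distogram_archive(dist_path) if dist_path.exists() else (None, None)
        decoys.append(Decoy(structure, dist, err))
    return DecoyPool(decoys)
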