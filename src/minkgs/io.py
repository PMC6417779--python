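"""File formats: pedigree/phenotype TSV, PLINK PED/MAP dialect, HDF5
haplotype container, YAML configuration, JSON run manifests.

PLINK convention used here: alleles coded A/B, missing as "0 0", MAP
positions 1-based base pairs under the 1 cM = 1 Mb convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeMap
from .pedigree import FEMALE, MALE, Pedigree
from .simulate import SimConfig

_SEX_OUT = {MALE: "M", FEMALE: "F"}
_SEX_IN = {"M": MALE, "F": FEMALE, "1": MALE, "2": FEMALE}
_UNKNOWN_CODES = {"0", "NA", ""}


def write_pedigree(path, ped: Pedigree, tbv=None, phenotype=None,
                   ids=None) -> None:
    """Pedigree TSV: id, sire, dam, sex, generation[, tbv, phenotype].

    Row index i is written as id i+1 (1-based); unknown parents as 0.
    """
    ids = np.arange(1, ped.n + 1) if ids is None else np.asarray(ids)
    code = np.concatenate([[0], ids])  # parent -1 -> 0
    df = pd.DataFrame({
        "id": ids,
        "sire": code[ped.sire + 1],
        "dam": code[ped.dam + 1],
        "sex": [_SEX_OUT[s] for s in ped.sex],
        "generation": ped.generation,
    })
    if tbv is not None:
        df["tbv"] = tbv
    if phenotype is not None:
        df["phenotype"] = phenotype
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> tuple[Pedigree, pd.DataFrame]:
    """Read and topologically order a pedigree TSV.

    Accepts columns id, sire, dam and optionally sex, generation; 0 or NA
    denotes an unknown parent.  Returns the ordered pedigree and the
    reordered source frame (with a ``row`` column giving the new index).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    if df.empty:
        return Pedigree(np.empty(0, int), np.empty(0, int),
                        np.empty(0, np.int8), np.empty(0, int)), df
    ids = df["id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree file")
    known = set(ids)
    parents = {}
    for _, r in df.iterrows():
        s = r["sire"] if r["sire"] not in _UNKNOWN_CODES else None
        d = r["dam"] if r["dam"] not in _UNKNOWN_CODES else None
        for p in (s, d):
            if p is not None and p not in known:
                raise ValueError(f"parent {p} of {r['id']} has no own record")
        parents[r["id"]] = (s, d)
    # Kahn's algorithm: parents before offspring
    order, placed = [], set()
    pending = list(ids)
    while pending:
        rest = []
        for i in pending:
            s, d = parents[i]
            if (s is None or s in placed) and (d is None or d in placed):
                order.append(i)
                placed.add(i)
            else:
                rest.append(i)
        if len(rest) == len(pending):
            raise ValueError("pedigree contains a cycle")
        pending = rest
    row_of = {i: k for k, i in enumerate(order)}
    df = df.set_index("id").loc[order].reset_index()
    df["row"] = np.arange(len(df))
    sire = np.array([row_of[s] if s is not None else -1
                     for s, _ in (parents[i] for i in order)])
    dam = np.array([row_of[d] if d is not None else -1
                    for _, d in (parents[i] for i in order)])
    if "sex" in df:
        sex = np.array([_SEX_IN.get(str(v), MALE) for v in df["sex"]], np.int8)
    else:
        # infer from parental roles where possible
        sex = np.zeros(len(order), np.int8)
        sex[dam[dam >= 0]] = FEMALE
        sex[sire[sire >= 0]] = MALE
    gen = (df["generation"].astype(int).to_numpy()
           if "generation" in df else np.zeros(len(order), int))
    ped = Pedigree(sire, dam, sex, gen)
    ped.validate()
    return ped, df


def write_phenotypes(path, ids, values) -> None:
    pd.DataFrame({"id": ids, "value": values}).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_plink(prefix, dosage: np.ndarray, chrom: np.ndarray,
                pos_cm: np.ndarray, ids=None, sex=None) -> None:
    """Write PED/MAP; dosage counts B alleles, -1 is missing."""
    prefix = Path(prefix)
    n, m = dosage.shape
    ids = np.arange(1, n + 1) if ids is None else ids
    sex_code = np.full(n, 0) if sex is None else np.where(np.asarray(sex) == MALE, 1, 2)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(m):
            bp = int(round(pos_cm[j] * 1e6)) + 1
            fh.write(f"{int(chrom[j]) + 1}\tM{j + 1}\t{pos_cm[j]:.6f}\t{bp}\n")
    geno_str = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(n):
            cells = [geno_str[int(d)] for d in dosage[i]]
            fh.write(f"FAM\t{ids[i]}\t0\t0\t{sex_code[i]}\t-9\t"
                     + "\t".join(cells) + "\n")


def read_plink(prefix) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Read the PED/MAP dialect back into (dosage, map frame, ids)."""
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                     names=["chrom", "snp", "cm", "bp"])
    m = len(mp)
    dosages, ids = [], []
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2,
            ("0", "0"): -1}
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            f = line.split()
            if len(f) != 6 + 2 * m:
                raise ValueError("PED row length does not match the MAP")
            ids.append(f[1])
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                pair = (f[6 + 2 * j], f[7 + 2 * j])
                if pair not in code:
                    raise ValueError(f"allele codes {pair} outside {{A,B,0}}")
                row[j] = code[pair]
            dosages.append(row)
    return np.array(dosages), mp, ids


def write_map(path, gmap: GenomeMap) -> None:
    pd.DataFrame({
        "chrom": gmap.locus_chrom + 1,
        "locus": np.arange(1, gmap.n_loci + 1),
        "cm": gmap.locus_pos,
        "class": gmap.locus_class,
        "n_alleles": gmap.n_alleles,
    }).to_csv(path, sep="\t", index=False)


def save_haplotypes(path, haps: np.ndarray, gmap: GenomeMap,
                    ids=None) -> None:
    """Compact HDF5 container (int8 haplotypes plus the genome map)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("haplotypes", data=haps, compression="gzip")
        g = f.create_group("map")
        g.create_dataset("chrom_lengths", data=gmap.chrom_lengths)
        g.create_dataset("locus_chrom", data=gmap.locus_chrom)
        g.create_dataset("locus_pos", data=gmap.locus_pos)
        g.create_dataset("locus_class", data=gmap.locus_class)
        g.create_dataset("n_alleles", data=gmap.n_alleles)
        if ids is not None:
            f.create_dataset("ids", data=np.asarray(ids))
        f.attrs["version"] = __version__


def load_haplotypes(path):
    with h5py.File(path, "r") as f:
        haps = f["haplotypes"][...]
        g = f["map"]
        gmap = GenomeMap(g["chrom_lengths"][...], g["locus_chrom"][...],
                         g["locus_pos"][...], g["locus_class"][...],
                         g["n_alleles"][...])
        ids = f["ids"][...] if "ids" in f else None
    return haps, gmap, ids


def save_matrix(path, m: np.ndarray) -> None:
    """Relationship-matrix export: plain text (.txt) or compressed
    binary (.npz) by extension."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, matrix=np.asarray(m))
    else:
        np.savetxt(path, np.asarray(m), fmt="%.10g")


def load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        return np.load(path)["matrix"]
    return np.loadtxt(path)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**raw)


def dump_config(config: SimConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: SimConfig, seeds: dict,
                   outputs: list) -> Path:
    """JSON manifest: config snapshot, seeds, version, output checksums —
    enough to reproduce every artifact bit for bit."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "minkgs",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
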