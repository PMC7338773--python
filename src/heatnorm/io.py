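"""Readers and writers for the pipeline's plain-text formats.

Pedigree, weather, phenotype and covariate tables travel as CSV;
genotypes as PLINK ``.raw``-style text or CSV; relationship matrices as
Matrix Market text with a JSON id sidecar; posterior chains as CSV with
a JSON metadata sidecar; gene annotation as GFF3 or BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from heatnorm.relationship import GenotypeSet, HInverse

# ---------------------------------------------------------------------------
# simple tables


def write_pedigree(pedigree: pd.DataFrame, path):
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    required = {"animal", "sire", "dam"}
    if not required <= set(ped.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    return ped


def write_weather(weather: pd.DataFrame, path):
    weather.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    w = pd.read_csv(path, parse_dates=["date"])
    return w


def write_phenotypes(records: pd.DataFrame, path):
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["conception", "farrowing"])


# ---------------------------------------------------------------------------
# genotypes


def write_raw(genotypes: GenotypeSet, path):
    """PLINK ``.raw``-style text: header then one animal per line.

    Columns: FID IID PAT MAT SEX PHENOTYPE then one dosage per SNP
    (``NA`` for missing).  SNP map (chrom/pos) goes in a ``.map``-style
    sidecar next to the file.
    """
    path = Path(path)
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{s}_A" for s in genotypes.snp_ids
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, animal in enumerate(genotypes.ids):
            row = [str(animal), str(animal), "0", "0", "0", "-9"]
            row += [
                "NA" if d < 0 else str(int(d)) for d in genotypes.dosages[i]
            ]
            fh.write(" ".join(row) + "\n")
    snp_map = pd.DataFrame(
        {
            "chrom": genotypes.chrom,
            "snp": genotypes.snp_ids,
            "pos": genotypes.pos,
        }
    )
    snp_map.to_csv(path.with_suffix(path.suffix + ".map"), sep="\t", index=False)


def read_raw(path) -> GenotypeSet:
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    snp_cols = df.columns[6:]
    snp_ids = np.array([c[:-2] if c.endswith("_A") else c for c in snp_cols])
    dosages = df[snp_cols].to_numpy(float)
    dosages = np.where(np.isnan(dosages), -1, dosages).astype(np.int8)
    map_path = path.with_suffix(path.suffix + ".map")
    if map_path.exists():
        snp_map = pd.read_csv(map_path, sep="\t").set_index("snp")
        chrom = snp_map.loc[snp_ids, "chrom"].to_numpy()
        pos = snp_map.loc[snp_ids, "pos"].to_numpy()
    else:
        chrom = np.ones(len(snp_ids), dtype=int)
        pos = np.arange(1, len(snp_ids) + 1)
    ids = df["IID"].to_numpy()
    return GenotypeSet(ids=ids, snp_ids=snp_ids, chrom=chrom, pos=pos, dosages=dosages)


def write_genotypes_csv(genotypes: GenotypeSet, path):
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.ids, columns=genotypes.snp_ids
    )
    df.index.name = "animal"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# covariate table with sidecar


def write_env_table(env_table, stats: dict, path):
    """Covariate CSV plus a JSON sidecar of per-column min/max/midpoint."""
    path = Path(path)
    df = env_table.data if hasattr(env_table, "data") else env_table
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(stats, fh, indent=1, default=float)


def read_env_table(path):
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    stats = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, stats


# ---------------------------------------------------------------------------
# matrices


def write_h_inverse(h_inverse: HInverse, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "h_inverse.mtx", sp.coo_matrix(h_inverse.matrix))
    meta = {
        "ids": [int(i) if np.issubdtype(type(i), np.integer) else str(i)
                for i in h_inverse.ids.tolist()],
        "n_genotyped": int(h_inverse.n_genotyped),
    }
    (outdir / "h_inverse_ids.json").write_text(json.dumps(meta))


def read_h_inverse(outdir) -> HInverse:
    outdir = Path(outdir)
    mat = sio.mmread(outdir / "h_inverse.mtx").tocsr()
    meta = json.loads((outdir / "h_inverse_ids.json").read_text())
    return HInverse(
        ids=np.asarray(meta["ids"]),
        matrix=mat,
        n_genotyped=meta["n_genotyped"],
    )


# ---------------------------------------------------------------------------
# chains


def write_chain(results, outdir):
    """Posterior chain CSV + metadata JSON + posterior-mean solutions CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.chain.to_csv(outdir / "varcomp_chain.csv", index=False)
    meta = dict(results.metadata)
    meta["class_boundaries"] = [float(b) for b in results.class_boundaries]
    meta["env_stats"] = {k: float(v) for k, v in results.env_stats.items()}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1, default=str))
    results.gebv().to_csv(outdir / "gebv.csv", index=False)
    pd.DataFrame(
        {"effect": results.fixed_names, "estimate": results.beta_mean}
    ).to_csv(outdir / "fixed_effects.csv", index=False)


# ---------------------------------------------------------------------------
# gene annotation


def read_gff3(path, feature_types=("gene",)) -> pd.DataFrame:
    """Gene intervals from a GFF3 file as half-open [start, end).

    GFF3 is 1-based inclusive; the returned ``start`` is converted to
    0-based so that ``end`` becomes exclusive.  The gene identifier is
    taken from ``ID=`` or ``gene_id=`` attributes, else ``Name=``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name", "NA")
            rows.append(
                (parts[0], int(parts[3]) - 1, int(parts[4]), gene)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def read_bed(path) -> pd.DataFrame:
    """BED intervals (already half-open, 0-based)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
    )
    return df
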