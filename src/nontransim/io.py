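"""File readers and writers for the pipeline's tabular and sequence formats.

CSV headers are documented here and round-trip exactly through the paired
reader/writer.  Competition time courses carry their competitor ids as
``#key=value`` comment lines above the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .simcore.sim_types import CompetitionTimecourse, Timepoint
from .transitivity import PairwiseFitnessMatrix


def write_timecourse(tc: CompetitionTimecourse, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#competitor_a={tc.competitor_a}\n")
        fh.write(f"#competitor_b={tc.competitor_b}\n")
        fh.write("generation,count_a,count_b,sample_size\n")
        for tp in tc.timepoints:
            fh.write(f"{tp.generation},{tp.count_a},{tp.count_b},{tp.sample_size}\n")


def read_timecourse(path) -> CompetitionTimecourse:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
            body_start = i + 1
        else:
            break
    header = lines[body_start].strip().split(",")
    expected = ["generation", "count_a", "count_b", "sample_size"]
    if header != expected:
        raise ValueError(f"bad time-course header {header}, expected {expected}")
    tps = []
    for line in lines[body_start + 1 :]:
        if not line.strip():
            continue
        g, a, b, n = line.strip().split(",")
        tps.append(Timepoint(int(g), float(a), float(b), float(n)))
    return CompetitionTimecourse(
        meta.get("competitor_a", "a"), meta.get("competitor_b", "b"), tps
    )


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["population", "generation", "killing", "immunity"])


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["population", "generation", "variant_id", "frequency"])


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    return list(SeqIO.parse(str(path), "fastq"))


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path):
    return list(SeqIO.parse(str(path), "fasta"))


def write_matrix(matrix: PairwiseFitnessMatrix, path) -> None:
    """Long-format matrix CSV: earlier_id,later_id,f0,s_hat,stderr."""
    rows = []
    for (earlier, later), entries in matrix.entries.items():
        for e in entries:
            rows.append(
                {"earlier_id": earlier, "later_id": later, "f0": e.f0,
                 "s_hat": e.s_hat, "stderr": e.stderr}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrix(path) -> PairwiseFitnessMatrix:
    df = pd.read_csv(path)
    clones: list[str] = []
    for col in ("earlier_id", "later_id"):
        for c in df[col]:
            if c not in clones:
                clones.append(c)
    m = PairwiseFitnessMatrix(clones)
    for r in df.itertuples():
        stderr = None if pd.isna(r.stderr) else float(r.stderr)
        f0 = None if pd.isna(r.f0) else float(r.f0)
        m.add(r.earlier_id, r.later_id, float(r.s_hat), stderr, f0)
    return m


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
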