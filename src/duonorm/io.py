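"""Text-format readers and writers (TSV, GMT, FASTA, JASPAR, YAML).

Everything is plain text so pipeline artifacts survive source trees and
diffs; FASTA goes through Biopython, tables through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .normalize import ExpressionMatrix
from .synthdata import AnnotationSet, CtTable, ProbeLevelDataset, PromoterSet

__all__ = [
    "write_probe_tsv",
    "read_probe_tsv",
    "write_truth_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gmt",
    "read_gmt",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "write_jaspar",
    "read_jaspar",
    "write_ct_tsv",
    "read_ct_tsv",
    "load_yaml",
    "dump_yaml",
    "read_candidate_table",
    "count_gene_candidates",
]


def write_probe_tsv(dataset: ProbeLevelDataset, path: str | Path) -> None:
    P, J, N = dataset.intensities.shape
    rows = {
        "probeset_id": np.repeat(dataset.probeset_ids, J),
        "probe_index": np.tile(np.arange(J), P),
    }
    flat = dataset.intensities.reshape(P * J, N)
    for j, sid in enumerate(dataset.sample_ids):
        rows[sid] = flat[:, j]
    header = "# groups: " + ",".join(dataset.group_labels.tolist())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_probe_tsv(path: str | Path, groups: tuple[str, str] = ("EXP", "REF")) -> ProbeLevelDataset:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# groups:"):
            raise ValueError("missing '# groups:' header line")
        labels = np.array(first.split(":", 1)[1].strip().split(","))
        df = pd.read_csv(fh, sep="\t")
    sample_ids = [c for c in df.columns if c not in ("probeset_id", "probe_index")]
    probesets = list(dict.fromkeys(df["probeset_id"]))
    J = int(df["probe_index"].max()) + 1
    values = df[sample_ids].to_numpy().reshape(len(probesets), J, len(sample_ids))
    return ProbeLevelDataset(
        intensities=values,
        probeset_ids=probesets,
        sample_ids=sample_ids,
        group_labels=labels,
        groups=groups,
    )


def write_truth_tsv(dataset: ProbeLevelDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"probeset_id": list(dataset.truth), "effect_log2": list(dataset.truth.values())}
    ).to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probeset_ids, columns=matrix.sample_ids)
    df.index.name = "probeset_id"
    with open(path, "w") as fh:
        fh.write(f"# normalization: {matrix.normalization_tag}\n")
        df.to_csv(fh, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline()
        tag = first.split(":", 1)[1].strip() if first.startswith("# normalization:") else "unknown"
        df = pd.read_csv(fh, sep="\t", index_col="probeset_id")
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns), tag)


def write_gmt(annotation: AnnotationSet, path: str | Path) -> None:
    term_module = {
        t: module for module, tids in annotation.planted_modules.items() for t in tids
    }
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            genes = "\t".join(sorted(annotation.terms[term]))
            desc = f"planted:{term_module[term]}" if term in term_module else "na"
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationSet:
    terms: dict[str, set[str]] = {}
    planted: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], set(parts[2:])
            terms[term] = genes
            if desc.startswith("planted:"):
                planted.setdefault(desc.split(":", 1)[1], set()).add(term)
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return AnnotationSet(terms=terms, universe=universe, planted_modules=planted)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    records = []
    for gene in promoters.genes():
        for species, seqs in (("rat", promoters.rat), ("ortholog", promoters.ortholog)):
            records.append(
                SeqRecord(
                    Seq(seqs[gene]),
                    id=f"{gene}|{species}|{-promoters.length}",
                    description="",
                )
            )
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path: str | Path) -> PromoterSet:
    rat: dict[str, str] = {}
    ortho: dict[str, str] = {}
    length = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, species, _off = rec.id.split("|")
        seq = str(rec.seq).upper()
        length = max(length, len(seq))
        (rat if species == "rat" else ortho)[gene] = seq
    return PromoterSet(length=length, rat=rat, ortholog=ortho)


def write_jaspar(pwms, path: str | Path) -> None:
    """JASPAR-format PWM text (counts scaled to 100)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            for base, row in zip("ACGT", np.round(pwm.matrix * 100, 2)):
                fh.write(f"{base}  [ " + "  ".join(f"{v:g}" for v in row) + " ]\n")


def read_jaspar(path: str | Path):
    """Parse JASPAR-format PWMs via Bio.motifs."""
    from Bio import motifs

    from .footprint import Pwm

    out = []
    with open(path) as fh:
        for motif in motifs.parse(fh, "jaspar"):
            counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)
            out.append(Pwm.from_counts(counts, id=motif.matrix_id or motif.name))
    return out


def write_ct_tsv(table: CtTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference_genes: {','.join(table.reference_genes)}\n")
        fh.write(f"# control_group: {table.control_group}\n")
        table.records.to_csv(fh, sep="\t", index=False)


def read_ct_tsv(path: str | Path) -> CtTable:
    refs: list[str] = []
    control = "NoRecall"
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# reference_genes:"):
                refs = line.split(":", 1)[1].strip().split(",")
            elif line.startswith("# control_group:"):
                control = line.split(":", 1)[1].strip()
            else:
                fh.seek(pos)
                break
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    return CtTable(records=df, reference_genes=refs, control_group=control)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


# --- candidate-list tables (published supplementary layout) ---------------

_CANDIDATE_MARK = "Gene candidate"


def _find_col(df: pd.DataFrame, norm: str, stat: str) -> str:
    norm = norm.lower()
    stat = stat.lower()
    for col in df.columns:
        c = col.lower()
        if not c.startswith(norm):
            continue
        if stat == "vip" and "viplow" in c:
            continue
        if stat in c:
            return col
    raise KeyError(f"no column for {norm}*{stat} in {list(df.columns)}")


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a published-style candidate list (TSV or XLSX).

    Expected columns: a probe id column, a candidates column whose flagged
    rows read 'Gene candidate', and per-normalization columns named
    ``MAS*``/``RMA*`` containing ``log2fc``, ``limmap``, ``vip`` and
    ``viplow``.  Returns a tidy frame indexed by probeset id with columns
    log2fc_mas, log2fc_rma, p_mas, p_rma, vip_mas, vip_rma, viplow_mas,
    viplow_rma, is_candidate.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep="\t")
    id_col = next(
        (c for c in raw.columns if "probe" in c.lower() or c.lower() in ("id", "probeset_id")),
        raw.columns[0],
    )
    cand_col = next((c for c in raw.columns if "candidate" in c.lower()), None)
    if cand_col is None:
        raise ValueError("no candidates column found")
    out = pd.DataFrame(index=pd.Index(raw[id_col], name="probeset_id"))
    for norm, suffix in (("mas", "mas"), ("rma", "rma")):
        out[f"log2fc_{suffix}"] = raw[_find_col(raw, norm, "log2fc")].to_numpy()
        out[f"p_{suffix}"] = raw[_find_col(raw, norm, "limmap")].to_numpy()
        out[f"vip_{suffix}"] = raw[_find_col(raw, norm, "vip")].to_numpy()
        out[f"viplow_{suffix}"] = raw[_find_col(raw, norm, "viplow")].to_numpy()
    out["is_candidate"] = (raw[cand_col].astype(str).str.strip() == _CANDIDATE_MARK).to_numpy()
    return out


def count_gene_candidates(table: pd.DataFrame) -> int:
    return int(table["is_candidate"].sum())
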