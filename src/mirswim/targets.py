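"""Target-prediction consensus and a built-in seed-match scanner.

External predictors (e.g. RNAhybrid, miRanda, TargetScan) are consumed as
per-tool vote lists; a (miRNA, gene) pair supported by at least two of three
tools becomes a putative target call (gene-level agreement).  The seed
scanner is a self-contained stand-in predictor reporting canonical
7mer-m8 / 7mer-A1 / 8mer seed sites, so consensus logic is testable without
running any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import revcomp

__all__ = [
    "TargetVote", "TargetCall", "SeedSite",
    "consensus", "seed_scan", "annotate_genes",
    "read_votes_tsv", "write_calls_tsv",
]


@dataclass(frozen=True)
class TargetVote:
    mirna: str
    gene: str
    tool: str


@dataclass
class TargetCall:
    mirna: str
    gene: str
    tools: tuple[str, ...]
    gene_description: str = ""

    @property
    def n_tools(self) -> int:
        return len(self.tools)


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site on a transcript (0-based half-open)."""

    start: int
    end: int
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1


def consensus(votes: list[TargetVote], min_tools: int = 2) -> list[TargetCall]:
    """Calls supported by >= min_tools distinct tools (monotone in threshold)."""
    if not 1 <= min_tools <= 3:
        raise ValueError("min_tools must be in 1..3")
    by_pair: dict[tuple[str, str], set[str]] = {}
    for v in votes:
        by_pair.setdefault((v.mirna, v.gene), set()).add(v.tool)
    calls = [
        TargetCall(mirna=m, gene=g, tools=tuple(sorted(tools)))
        for (m, g), tools in by_pair.items()
        if len(tools) >= min_tools
    ]
    calls.sort(key=lambda c: (c.mirna, c.gene))
    return calls


def seed_scan(mirna_seq: str, transcript_seq: str) -> list[SeedSite]:
    """Canonical seed sites of a miRNA on a transcript.

    The transcript-side match for miRNA positions 2-7 (5'->3') is the
    reverse complement of that 6-mer.  A site extends to 7mer-m8 when the
    transcript base 5' of the core pairs miRNA position 8, to 7mer-A1 when
    an A sits opposite miRNA position 1, and to 8mer with both.  Sites with
    neither extension (plain 6mers) are not reported.
    """
    if len(mirna_seq) < 18:
        raise ValueError("miRNA sequence must be at least 18 nt")
    if not transcript_seq:
        raise ValueError("transcript must be non-empty")
    mir = mirna_seq.upper().replace("U", "T")
    tx = transcript_seq.upper().replace("U", "T")
    core = revcomp(mir[1:7])          # pairs miRNA 2-7
    m8_base = revcomp(mir[7])          # transcript base pairing position 8
    sites = []
    pos = tx.find(core)
    while pos != -1:
        has_m8 = pos > 0 and tx[pos - 1] == m8_base
        has_a1 = pos + 6 < len(tx) and tx[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(pos - 1, pos + 7, "8mer"))
        elif has_m8:
            sites.append(SeedSite(pos - 1, pos + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(pos, pos + 7, "7mer-A1"))
        pos = tx.find(core, pos + 1)
    return sites


def annotate_genes(
    calls: list[TargetCall], gene_info: pd.DataFrame
) -> tuple[list[TargetCall], list[str]]:
    """Attach descriptions from an NCBI gene_info table (left join).

    Genes missing from the table keep description "NA" and are returned in
    the warning list rather than dropped.
    """
    cols = {c.lstrip("#").lower(): c for c in gene_info.columns}
    gene_col = cols.get("geneid")
    desc_col = cols.get("description")
    if gene_col is None or desc_col is None:
        raise ValueError("gene_info needs GeneID and description columns")
    desc = dict(zip(gene_info[gene_col].astype(str), gene_info[desc_col].astype(str)))
    missing = []
    out = []
    for c in calls:
        d = desc.get(str(c.gene))
        if d is None:
            d = "NA"
            missing.append(c.gene)
        out.append(TargetCall(c.mirna, c.gene, c.tools, d))
    return out, missing


def read_votes_tsv(path) -> list[TargetVote]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mirna", "gene", "tool"}
    if not need.issubset(df.columns):
        raise ValueError(f"vote file needs columns {sorted(need)}")
    return [TargetVote(r.mirna, r.gene, r.tool) for r in df.itertuples()]


def load_gene_info(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_calls_tsv(calls: list[TargetCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tn_tools\ttools\tdescription\n")
        for c in calls:
            fh.write(f"{c.mirna}\t{c.gene}\t{c.n_tools}\t"
                     f"{','.join(c.tools)}\t{c.gene_description}\n")
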