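"""Intronless-gene classification, MAE cross-tabulation and enrichment tests.

A gene is *intronless* when its transcripts contain a single exon.  The
strict rule (default) requires every transcript to be single-exon; a
lenient rule accepts genes with at least one single-exon transcript.
Over-representation of monoallelic-expression calls among intronless genes
is tested with Fisher's exact test on the 2×2 cross-tabulation; term-level
(GO-style) over-representation uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import GFF3ParseError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by start


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]


@dataclass
class EnrichmentResult:
    """Over-representation of a term (or contrast) in a gene set.

    k of the K set members carry the term; m of the M background genes do.
    """

    term_id: str
    k: int
    K: int
    m: int
    M: int
    odds_ratio: float
    p_value: float
    adjusted_p: Optional[float] = None
    haldane_corrected: bool = False


# ---------------------------------------------------------------------------
# GFF3


def _attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(text: str) -> list[GeneModel]:
    """Parse GFF3 text into gene models.

    Expects gene / mRNA (or transcript) / exon rows linked by ID/Parent.
    Coordinates stay 1-based inclusive; exons are stored sorted by start
    regardless of strand.  Raises :class:`GFF3ParseError` with the 1-based
    line number for a missing ``##gff-version 3`` pragma, malformed rows,
    ``end < start`` and orphan exons.

    Written in-house because the error contract (line-accurate diagnostics
    on plain text, no database) is the point of this reader.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##gff-version 3"):
        raise GFF3ParseError("missing '##gff-version 3' pragma", line=1)

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    transcripts: dict[str, Transcript] = {}
    transcript_gene: dict[str, str] = {}
    pending_exons: list[tuple[int, str, int, int]] = []  # line, parent, start, end

    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFF3ParseError(
                f"expected 9 tab-separated columns, got {len(fields)}", line=lineno
            )
        _, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GFF3ParseError("non-integer coordinates", line=lineno) from None
        if end < start:
            raise GFF3ParseError(f"end {end} < start {start}", line=lineno)
        attrs = _attributes(attr_s)

        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise GFF3ParseError("gene feature without ID", line=lineno)
            genes[gid] = GeneModel(gene_id=gid, transcripts=[])
            gene_order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            tid = attrs.get("ID")
            parent = attrs.get("Parent")
            if tid is None or parent is None:
                raise GFF3ParseError(
                    f"{ftype} feature needs ID and Parent", line=lineno
                )
            transcripts[tid] = Transcript(transcript_id=tid, strand=strand, exons=[])
            transcript_gene[tid] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise GFF3ParseError("exon feature without Parent", line=lineno)
            for p in parent.split(","):
                pending_exons.append((lineno, p, start, end))
        # other feature types are ignored

    for lineno, parent, start, end in pending_exons:
        tr = transcripts.get(parent)
        if tr is None:
            raise GFF3ParseError(
                f"orphan exon: unknown parent transcript {parent!r}", line=lineno
            )
        tr.exons.append((start, end))

    for tid, tr in transcripts.items():
        gid = transcript_gene[tid]
        gene = genes.get(gid)
        if gene is None:
            raise GFF3ParseError(f"transcript {tid!r} has unknown gene parent {gid!r}")
        if not tr.exons:
            raise GFF3ParseError(f"transcript {tid!r} has no exons")
        tr.exons.sort(key=lambda e: e[0])
        for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
            if s2 <= e1:
                raise GFF3ParseError(
                    f"overlapping exons in transcript {tid!r}: ({s1},{e1}) and ({s2},{e2})"
                )
        gene.transcripts.append(tr)

    return [genes[g] for g in gene_order]


# ---------------------------------------------------------------------------
# classification and tests


def classify_intronless(models: Iterable[GeneModel], rule: str = "strict") -> set[str]:
    """Gene ids classified intronless.

    strict: every transcript single-exon (default); lenient: at least one.
    Genes without transcripts are never intronless.
    """
    if rule not in ("strict", "lenient"):
        raise ParameterError("rule must be 'strict' or 'lenient'")
    out = set()
    for gene in models:
        if not gene.transcripts:
            continue
        single = [len(t.exons) == 1 for t in gene.transcripts]
        if (all(single) if rule == "strict" else any(single)):
            out.add(gene.gene_id)
    return out


def crosstab_mae(intronless: set[str], mae_table: pd.DataFrame) -> np.ndarray:
    """2×2 counts [[intronless∧MAE, intronless∧bi], [intronful∧MAE, intronful∧bi]].

    ``mae_table`` needs columns gene_id, mae_call with calls in
    {monoallelic, biallelic}.  Intronless genes absent from the table are
    excluded (logged).
    """
    calls = mae_table.set_index("gene_id")["mae_call"]
    bad = set(calls.unique()) - {"monoallelic", "biallelic"}
    if bad:
        raise ParameterError(f"unknown mae_call value(s): {sorted(bad)}")
    missing = intronless - set(calls.index)
    if missing:
        logger.info("crosstab_mae: %d intronless genes missing from MAE table", len(missing))
    table = np.zeros((2, 2), dtype=int)
    for gene_id, call in calls.items():
        row = 0 if gene_id in intronless else 1
        col = 0 if call == "monoallelic" else 1
        table[row, col] += 1
    return table


def fisher_exact(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    p sums all hypergeometric tables (fixed margins) whose probability
    does not exceed the observed one.  The odds ratio is the sample
    cross-product ratio, with a Haldane 0.5 correction (flagged) when any
    cell is zero.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if (t < 0).any():
        raise ParameterError("counts must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(
        term_id="2x2",
        k=a,
        K=a + b,
        m=a + c,
        M=int(t.sum()),
        odds_ratio=float(odds),
        p_value=float(p),
        haldane_corrected=haldane,
    )


def term_overrepresentation(
    gene_set: set[str],
    background: set[str],
    gene_term_map: pd.DataFrame,
    adjust: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in a gene set.

    Per term with m carriers among the M background genes, the upper-tail
    probability of observing >= k carriers in a set of size K.  Adjusted
    across terms with Benjamini–Hochberg (default) or Bonferroni; sorted
    ascending by adjusted then raw p.  Mapped genes outside the background
    are ignored (logged).
    """
    if not gene_set <= background:
        raise ParameterError("gene_set must be a subset of background")
    if adjust not in ("fdr_bh", "bonferroni"):
        raise ParameterError("adjust must be 'fdr_bh' or 'bonferroni'")
    mapped = gene_term_map[gene_term_map["gene_id"].isin(background)]
    dropped = len(gene_term_map) - len(mapped)
    if dropped:
        logger.info("term_overrepresentation: %d mappings outside background ignored", dropped)
    M, K = len(background), len(gene_set)
    results = []
    for term_id, genes in mapped.groupby("term_id")["gene_id"]:
        carriers = set(genes)
        m = len(carriers)
        k = len(carriers & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, m, K))
        in_set_non = K - k
        bg_car = m - k
        bg_non = (M - K) - bg_car
        if min(k, in_set_non, bg_car, bg_non) == 0:
            odds = (k + 0.5) * (bg_non + 0.5) / ((in_set_non + 0.5) * (bg_car + 0.5))
            hald = True
        else:
            odds = k * bg_non / (in_set_non * bg_car)
            hald = False
        results.append(
            EnrichmentResult(
                term_id=str(term_id), k=k, K=K, m=m, M=M,
                odds_ratio=float(odds), p_value=p, haldane_corrected=hald,
            )
        )
    if results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method=adjust)
        for r, ap in zip(results, adj):
            r.adjusted_p = float(ap)
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term_id))
    return results
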