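"""SQLite persistence and aggregate queries over scan results.

The store answers the survey questions the screen is built for: how many
structures have a per-category minimum below a cutoff, which category
holds each structure's single overall shortest distance, the 1 Å-binned
histogram of per-structure minima over [0, 50) Å, and the candidate
shortlist export.  Headline queries consider only primary distances from
the C-terminal carbonyl carbon to lysine Nε (for N-terminal lysines this
means Nε was selected over αN), mirroring how the survey statistics are
defined; pass ``pair_filter=None`` to lift the restriction.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ScanConfig
from .scan_classify import Category, DistanceRecord, StructureSummary
from .terminus_target import TargetKind, round_report

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS structures (
    structure_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS records (
    structure_id TEXT NOT NULL REFERENCES structures(structure_id)
        ON DELETE CASCADE,
    assembly_id TEXT NOT NULL,
    model_number INTEGER NOT NULL,
    source_label_asym TEXT, source_auth_asym TEXT, source_operator TEXT,
    ct_label TEXT,
    target_label_asym TEXT, target_auth_asym TEXT, target_operator TEXT,
    target_label TEXT,
    target_kind TEXT NOT NULL,
    source_atom TEXT NOT NULL,
    target_atom TEXT NOT NULL,
    distance REAL NOT NULL,
    priority_rank INTEGER NOT NULL,
    category TEXT NOT NULL,
    covalent INTEGER NOT NULL,
    same_residue INTEGER NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_records_structure ON records(structure_id);
CREATE INDEX IF NOT EXISTS idx_records_category ON records(category, distance);
CREATE TABLE IF NOT EXISTS summaries (
    structure_id TEXT NOT NULL REFERENCES structures(structure_id)
        ON DELETE CASCADE,
    category TEXT NOT NULL,
    min_distance REAL NOT NULL,
    record_count INTEGER NOT NULL,
    is_overall_shortest INTEGER NOT NULL,
    PRIMARY KEY (structure_id, category)
);
"""


@dataclass
class PairFilter:
    """Restrict queries to records with a given primary atom pair."""

    source_atom: str = "C"
    target_atom: str = "NZ"
    kinds: tuple[str, ...] = (TargetKind.LYSINE.value,
                              TargetKind.N_TERMINAL_LYSINE.value)


#: the headline query restriction: Ct atom C to lysine Nε
DEFAULT_PAIR_FILTER = PairFilter()


@dataclass
class HistogramBins:
    category: Category
    range: tuple[float, float]
    bin_width: float
    counts: np.ndarray  # one entry per bin_width interval


@dataclass
class ShortlistRow:
    structure_id: str
    assembly_id: str
    binder_chain: str
    ct_label: str
    target_chain: str
    target_label: str
    target_kind: str
    source_atom: str
    target_atom: str
    distance: float  # rounded to 0.1 Å
    category: str


class DistanceStore:
    """Single-file embedded relational store for scan output."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('schema_version', ?)",
            (str(SCHEMA_VERSION),))
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- persistence --------------------------------------------------------

    def persist(self, summary: StructureSummary,
                records: list[DistanceRecord]) -> None:
        """Store one structure's records and summary; idempotent per id
        (a re-scan replaces the previous rows)."""
        sid = summary.structure_id
        for rec in records:
            if rec.structure_id != sid:
                raise ValueError(
                    f"record for {rec.structure_id!r} under summary {sid!r}")
        with self.conn:
            self.conn.execute(
                "DELETE FROM structures WHERE structure_id = ?", (sid,))
            self.conn.execute(
                "INSERT INTO structures (structure_id) VALUES (?)", (sid,))
            self.conn.executemany(
                "INSERT INTO records VALUES "
                "(?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                [(
                    rec.structure_id, rec.assembly_id, rec.model_number,
                    rec.source_chain[0], rec.source_chain[1], rec.source_chain[2],
                    rec.ct_label,
                    rec.target_chain[0], rec.target_chain[1], rec.target_chain[2],
                    rec.target_label, rec.target_kind.value,
                    rec.primary.source_atom, rec.primary.target_atom,
                    rec.primary.distance, rec.primary.priority_rank,
                    rec.category.value, int(rec.covalent), int(rec.same_residue),
                ) for rec in records])
            overall = summary.overall_shortest
            self.conn.executemany(
                "INSERT INTO summaries VALUES (?,?,?,?,?)",
                [(
                    sid, cat.value, rec.primary.distance,
                    summary.record_count.get(cat, 0),
                    int(overall is not None and cat is overall.category),
                ) for cat, rec in summary.minima.items()])

    def structure_count(self) -> int:
        (n,) = self.conn.execute("SELECT COUNT(*) FROM structures").fetchone()
        return n

    # -- query helpers ------------------------------------------------------

    def _minima_query(self, category: Category | None,
                      pair_filter: PairFilter | None,
                      exclude_same_residue: bool = True,
                      exclude_covalent: bool = False):
        """Per-structure (and per-category) minima over filtered records."""
        clauses, params = [], []
        if category is not None:
            clauses.append("category = ?")
            params.append(category.value)
        if pair_filter is not None:
            clauses.append("source_atom = ? AND target_atom = ?")
            params.extend([pair_filter.source_atom, pair_filter.target_atom])
            clauses.append("target_kind IN (%s)" %
                           ",".join("?" * len(pair_filter.kinds)))
            params.extend(pair_filter.kinds)
        if exclude_same_residue:
            clauses.append("same_residue = 0")
        if exclude_covalent:
            clauses.append("covalent = 0")
        where = ("WHERE " + " AND ".join(clauses)) if clauses else ""
        sql = (f"SELECT structure_id, category, MIN(distance) "
               f"FROM records {where} GROUP BY structure_id, category")
        return self.conn.execute(sql, params).fetchall()

    # -- the survey queries --------------------------------------------------

    def count_structures_below(
            self, category: Category, cutoff: float,
            pair_filter: PairFilter | None = DEFAULT_PAIR_FILTER) -> int:
        """Number of structures whose per-category minimum (restricted to
        the pair filter) is strictly below *cutoff* Å."""
        if not isinstance(category, Category):
            raise ValueError(f"unknown category: {category!r}")
        rows = self._minima_query(category, pair_filter)
        return sum(1 for _, _, d in rows if d < cutoff)

    def shortest_category_counts(
            self, cutoff: float,
            pair_filter: PairFilter | None = DEFAULT_PAIR_FILTER,
    ) -> dict[Category, int]:
        """Each structure contributes once, to the category holding its
        overall shortest filtered distance; only structures whose shortest
        is < *cutoff* are counted."""
        per_structure: dict[str, tuple[float, str]] = {}
        for sid, cat, d in self._minima_query(None, pair_filter):
            best = per_structure.get(sid)
            # tie on distance: deterministic category order
            key = (d, [c.value for c in Category].index(cat))
            if best is None or key < best:
                per_structure[sid] = key
        counts = {cat: 0 for cat in Category}
        for d, cat_idx in per_structure.values():
            if d < cutoff:
                counts[list(Category)[cat_idx]] += 1
        return counts

    def minima_histogram(
            self, category: Category, config: ScanConfig | None = None,
            pair_filter: PairFilter | None = DEFAULT_PAIR_FILTER,
    ) -> HistogramBins:
        """Per-structure category minima binned over [0, 50) Å.

        Minima are interrogated cumulatively at ``fine_step`` (0.1 Å)
        increments, and the increments summed into ``bin_width`` (1 Å)
        bins; values at or beyond the upper bound are excluded.
        """
        config = config or ScanConfig()
        lo, hi = config.histogram_range
        minima = [d for _, _, d in self._minima_query(category, pair_filter)
                  if lo <= d < hi]
        n_fine = int(round((hi - lo) / config.fine_step))
        fine_edges = lo + config.fine_step * np.arange(n_fine + 1)
        increments, _ = np.histogram(minima, bins=fine_edges)
        per_bin = int(round(config.bin_width / config.fine_step))
        counts = increments.reshape(-1, per_bin).sum(axis=1)
        return HistogramBins(category=category, range=(lo, hi),
                             bin_width=config.bin_width, counts=counts)

    def export_shortlist(
            self, cutoff: float,
            category: Category = Category.HETEROMERIC,
            config: ScanConfig | None = None,
            pair_filter: PairFilter | None = DEFAULT_PAIR_FILTER,
            path: str | Path | None = None) -> list[ShortlistRow]:
        """Candidate shortlist: the minimal surviving record per structure.

        Covalent (< cutoff) and same-residue records are excluded before
        minima are taken; rows are sorted ascending by distance (ties by
        structure id then binder chain) and distances print at 0.1 Å.
        """
        config = config or ScanConfig()
        clauses = ["category = ?", "covalent = 0", "same_residue = 0"]
        params: list = [category.value]
        if pair_filter is not None:
            clauses.append("source_atom = ? AND target_atom = ?")
            params.extend([pair_filter.source_atom, pair_filter.target_atom])
            clauses.append("target_kind IN (%s)" %
                           ",".join("?" * len(pair_filter.kinds)))
            params.extend(pair_filter.kinds)
        clauses.append("distance < ?")
        params.append(cutoff)
        sql = (f"SELECT * FROM records WHERE {' AND '.join(clauses)} "
               f"ORDER BY structure_id, distance")
        best: dict[str, tuple[float, str, ShortlistRow]] = {}
        for rec in self.conn.execute(sql, params):
            (sid, asm, _model, _sl, s_auth, s_op, ct_label,
             _tl, t_auth, t_op, t_label, t_kind,
             s_atom, t_atom, dist, _rank, cat, _cov, _same) = rec
            row = ShortlistRow(
                structure_id=sid, assembly_id=asm,
                binder_chain=f"{s_auth}/{s_op}", ct_label=ct_label,
                target_chain=f"{t_auth}/{t_op}", target_label=t_label,
                target_kind=t_kind, source_atom=s_atom, target_atom=t_atom,
                distance=round_report(dist), category=cat)
            prev = best.get(sid)
            if prev is None or (dist, row.binder_chain) < prev[:2]:
                best[sid] = (dist, row.binder_chain, row)
        out = sorted((entry[2] for entry in best.values()),
                     key=lambda r: (r.distance, r.structure_id, r.binder_chain))
        if path is not None:
            write_shortlist_tsv(out, path)
        return out


SHORTLIST_COLUMNS = [
    "structure_id", "assembly_id", "binder_chain", "ct_residue",
    "target_chain", "target_residue", "target_kind",
    "atom_pair", "distance_A", "category",
]


def write_shortlist_tsv(rows: list[ShortlistRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SHORTLIST_COLUMNS)
        for r in rows:
            writer.writerow([
                r.structure_id, r.assembly_id, r.binder_chain, r.ct_label,
                r.target_chain, r.target_label, r.target_kind,
                f"{r.source_atom}-{r.target_atom}", f"{r.distance:.1f}",
                r.category,
            ])
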