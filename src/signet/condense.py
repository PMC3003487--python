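"""Condense a network to the links with the largest two-condition expression change.

Given per-gene expression under two experimental conditions, every link is
scored by the *product-difference* form

    score = v2(source) * v2(target) - v1(source) * v1(target)

where ``v_c(g)`` is the (optionally log2-transformed, optionally
variance-corrected) mean of gene *g*'s replicate values in condition *c*.
A positive score is a *startup* hypothesis (the mechanism gains weight in
condition 2), a negative one a *shutdown*.  Condensation keeps the top
fraction of each tail — e.g. the top 5% startups and the top 5% shutdowns —
ranked by score magnitude.  The formula is isolated behind
:func:`link_score` so an alternative scoring rule can be swapped in.

Overlay coloring maps each gene's per-condition expression onto a
green/white/red scale in [-1, 1] by ranks, with the dataset median at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    NoScorableLinksError,
    ParameterError,
    SignetError,
    UnmeasuredGeneError,
)
from .model import LinkKey, RegLink, RegNetwork, canonical_link_key

_EPSILON_SD = 1e-8

TRANSFORMS = ("raw", "log2")
SCORING_MODES = ("plain", "variance_corrected")


@dataclass
class ConditionPair:
    """Replicate expression values for two conditions, per gene.

    ``values`` maps gene symbol to a pair of replicate tuples (condition 1,
    condition 2); each gene needs at least one value per condition.  With
    ``transform="log2"`` raw intensities must be strictly positive.  In
    ``variance_corrected`` scoring mode each gene's (transformed) values
    are divided by the gene's pooled standard deviation over all samples of
    both conditions, floored at 1e-8.
    """

    values: Dict[str, Tuple[tuple, tuple]]
    transform: str = "raw"
    scoring_mode: str = "plain"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ParameterError(f"transform must be one of {TRANSFORMS}")
        if self.scoring_mode not in SCORING_MODES:
            raise ParameterError(f"scoring_mode must be one of {SCORING_MODES}")
        for gene, (v1, v2) in self.values.items():
            if len(v1) < 1 or len(v2) < 1:
                raise ParameterError(f"gene {gene!r} needs >=1 value per condition")
            if self.transform == "log2" and (min(v1) <= 0 or min(v2) <= 0):
                raise ParameterError(
                    f"gene {gene!r}: log2 transform requires strictly positive intensities"
                )

    @property
    def genes(self) -> set:
        return set(self.values)

    def swapped(self) -> "ConditionPair":
        """Exchange the two condition labels (used for antisymmetry checks)."""
        return replace(
            self, values={g: (v2, v1) for g, (v1, v2) in self.values.items()}
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        condition_of: Dict[str, int],
        transform: str = "raw",
        scoring_mode: str = "plain",
    ) -> "ConditionPair":
        """Genes-x-samples DataFrame plus a column -> condition (1/2) map.

        Duplicate index entries (probe-level rows mapping to one gene) are
        collapsed by the per-sample mean before splitting into conditions.
        """
        cols1 = [c for c in frame.columns if condition_of.get(c) == 1]
        cols2 = [c for c in frame.columns if condition_of.get(c) == 2]
        if not cols1 or not cols2:
            raise ParameterError("each condition needs at least one sample column")
        collapsed = frame.groupby(level=0, sort=False).mean()
        values = {
            str(gene): (
                tuple(float(x) for x in row[cols1]),
                tuple(float(x) for x in row[cols2]),
            )
            for gene, row in collapsed.iterrows()
        }
        return cls(values=values, transform=transform, scoring_mode=scoring_mode)

    @classmethod
    def from_tsv(
        cls, source, transform: str = "raw", scoring_mode: str = "plain"
    ) -> "ConditionPair":
        """Read the two-header-line expression TSV.

        Line 1 names the columns (first column: gene symbol), line 2
        assigns each sample column to condition ``1`` or ``2``; remaining
        lines hold one gene (or probe) per row.
        """
        from .io import _open_read

        handle, close = _open_read(source)
        try:
            lines = handle.read().splitlines()
        finally:
            if close:
                handle.close()
        lines = [l for l in lines if l.strip()]
        if len(lines) < 2:
            raise ParameterError("expression table needs two header lines")
        header = lines[0].split("\t")
        conditions = lines[1].split("\t")
        samples = header[1:]
        if len(conditions) < len(header):
            raise ParameterError("condition-assignment line is shorter than the header")
        condition_of = {}
        for sample, tag in zip(samples, conditions[1:]):
            tag = tag.strip()
            if tag not in ("1", "2"):
                raise ParameterError(
                    f"condition for sample {sample!r} must be '1' or '2', got {tag!r}"
                )
            condition_of[sample] = int(tag)
        records = []
        for line in lines[2:]:
            cells = line.split("\t")
            records.append([cells[0]] + [float(x) for x in cells[1 : len(header)]])
        frame = pd.DataFrame(records, columns=header).set_index(header[0])
        return cls.from_dataframe(frame, condition_of, transform, scoring_mode)

    def to_tsv(self, dest=None, gene_column: str = "gene") -> Optional[str]:
        genes = sorted(self.values)
        n1 = len(next(iter(self.values.values()))[0]) if genes else 0
        n2 = len(next(iter(self.values.values()))[1]) if genes else 0
        header = (
            [gene_column]
            + [f"c1_r{i + 1}" for i in range(n1)]
            + [f"c2_r{i + 1}" for i in range(n2)]
        )
        cond_line = ["condition"] + ["1"] * n1 + ["2"] * n2
        rows = [
            "\t".join(header),
            "\t".join(cond_line),
        ]
        for gene in genes:
            v1, v2 = self.values[gene]
            rows.append(
                "\t".join([gene] + [repr(float(x)) for x in (*v1, *v2)])
            )
        text = "\n".join(rows) + "\n"
        if dest is None:
            return text
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text)
        return None


def _transformed(pair: ConditionPair, gene: str) -> Tuple[np.ndarray, np.ndarray]:
    if gene not in pair.values:
        raise UnmeasuredGeneError(f"gene {gene!r} has no expression values")
    v1, v2 = pair.values[gene]
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if pair.transform == "log2":
        a = np.log2(a)
        b = np.log2(b)
    return a, b


def gene_values(pair: ConditionPair, gene: str) -> Tuple[float, float]:
    """Per-condition expression value of a gene: the mean over replicates.

    In ``variance_corrected`` mode both replicate vectors are first divided
    by the gene's pooled standard deviation across all samples of both
    conditions (floored at 1e-8, so a zero-variance gene keeps v1 == v2).
    """
    a, b = _transformed(pair, gene)
    if pair.scoring_mode == "variance_corrected":
        pooled = np.concatenate([a, b])
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        scale = max(sd, _EPSILON_SD)
        a = a / scale
        b = b / scale
    return float(a.mean()), float(b.mean())


def link_score(link: RegLink, pair: ConditionPair) -> float:
    """Change-along-a-link score ``v2(s)*v2(t) - v1(s)*v1(t)``.

    Positive scores support a startup, negative a shutdown hypothesis; the
    rule applies identically to all three link types.  Raises
    :class:`~signet.errors.UnmeasuredGeneError` when either endpoint is
    unmeasured (callers exclude such links and count them).
    """
    v1s, v2s = gene_values(pair, link.source)
    v1t, v2t = gene_values(pair, link.target)
    return v2s * v2t - v1s * v1t


@dataclass(frozen=True)
class LinkScoreRecord:
    """One scored link with its tail classification and within-class rank."""

    link_key: LinkKey
    score: float
    link_class: str  # "startup" | "shutdown" | "unchanged"
    rank_within_class: int


@dataclass(frozen=True)
class CondensedNetwork:
    """The retained top-fraction startup/shutdown links of a condensation."""

    retained: tuple
    fraction: float
    n_scored: int
    n_unscored: int

    @property
    def startups(self) -> List[LinkScoreRecord]:
        return [r for r in self.retained if r.link_class == "startup"]

    @property
    def shutdowns(self) -> List[LinkScoreRecord]:
        return [r for r in self.retained if r.link_class == "shutdown"]

    def retained_keys(self) -> set:
        return {r.link_key for r in self.retained}


def condense(
    net: RegNetwork, pair: ConditionPair, fraction: float
) -> CondensedNetwork:
    """Score every scorable link and keep the top-``fraction`` of each tail.

    Each tail independently retains ``floor(fraction * n_scored)`` links
    (at least one whenever any link of that sign exists), ranked by score
    magnitude with ties broken by canonical link key.  Links with an
    unmeasured endpoint are excluded and counted in ``n_unscored``.
    """
    if not (0 < fraction <= 1):
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    scored: List[Tuple[LinkKey, float]] = []
    n_unscored = 0
    for link in net.links:
        try:
            s = link_score(link, pair)
        except UnmeasuredGeneError:
            n_unscored += 1
            continue
        scored.append((canonical_link_key(link), s))
    n_scored = len(scored)
    if n_scored == 0:
        raise NoScorableLinksError(
            "no link has both endpoints measured; nothing to condense"
        )
    per_tail = math.floor(fraction * n_scored)
    startups = sorted(
        ((k, s) for k, s in scored if s > 0),
        key=lambda ks: (-abs(ks[1]), ks[0].sort_key()),
    )
    shutdowns = sorted(
        ((k, s) for k, s in scored if s < 0),
        key=lambda ks: (-abs(ks[1]), ks[0].sort_key()),
    )
    retained: List[LinkScoreRecord] = []
    for tail, label in ((startups, "startup"), (shutdowns, "shutdown")):
        keep = min(len(tail), max(per_tail, 1) if tail else 0)
        for rank, (key, s) in enumerate(tail[:keep], start=1):
            retained.append(LinkScoreRecord(key, s, label, rank))
    return CondensedNetwork(
        retained=tuple(retained),
        fraction=fraction,
        n_scored=n_scored,
        n_unscored=n_unscored,
    )


@dataclass(frozen=True)
class OverlayRow:
    """Green/white/red pie-slice colors for one gene under both conditions.

    Colors lie in [-1, 1]: -1 full green (lowest expression), 0 white
    (dataset median), +1 full red (highest).  Unmeasured genes carry NaN.
    """

    symbol: str
    slice1_color: float
    slice2_color: float

    @property
    def measured(self) -> bool:
        return not math.isnan(self.slice1_color)


def _rank_colors(values: np.ndarray) -> np.ndarray:
    n = len(values)
    if n == 1:
        return np.zeros(1)
    ranks = rankdata(values)  # average ranks for ties
    mid = (n + 1) / 2.0
    colors = np.empty(n)
    above = ranks >= mid
    colors[above] = (ranks[above] - mid) / (n - mid)
    colors[~above] = (ranks[~above] - mid) / (mid - 1.0)
    return colors


def overlay_colors(net: RegNetwork, pair: ConditionPair) -> List[OverlayRow]:
    """Rank-based overlay colors for every node of the network.

    Per condition, measured genes are ranked and mapped piecewise-linearly
    so the dataset median is white (0), the minimum full green (-1) and the
    maximum full red (+1) — monotone in the underlying expression value.
    Variance correction does not apply here; only the transform is used.
    """
    plain = replace(pair, scoring_mode="plain")
    measured = [g for g in net.nodes if g in plain.values]
    if not measured:
        raise SignetError("no gene of the network is measured")
    v1 = np.array([gene_values(plain, g)[0] for g in measured])
    v2 = np.array([gene_values(plain, g)[1] for g in measured])
    c1 = dict(zip(measured, _rank_colors(v1)))
    c2 = dict(zip(measured, _rank_colors(v2)))
    nan = float("nan")
    return [
        OverlayRow(
            symbol=g,
            slice1_color=float(c1.get(g, nan)),
            slice2_color=float(c2.get(g, nan)),
        )
        for g in net.nodes
    ]
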