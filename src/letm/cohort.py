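"""Cohort assembly: multilocus recapture matching and incidence summaries.

Individuals are tracked between two electrofishing sessions (spring, fall)
without tags by matching multilocus genotypes. A spring/fall pair counts as a
recapture when the genotypes are identical or distant by at most one allele
summed across co-scored loci (allowing for a single genotyping error). The
allele distance at one locus is the size of the multiset difference between
the two unordered allele pairs (0, 1 or 2); missing loci are excluded
pairwise, and a comparison needs a minimum number of co-scored loci to be
valid. Any genotype with more than one candidate within the tolerance is
flagged ambiguous and excluded from the matched set rather than assigned
arbitrarily. Matching is done within each channel reach separately by the
caller.

Incidence tables report exact counts and percentages of mature males per
grouping (family x environment, sire type, ...); a group with no males has
undefined incidence, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from letm.model import validate_cohort

SESSIONS = ("spring", "fall")


@dataclass(frozen=True)
class MultilocusGenotype:
    """One individual's genotype: unordered allele pair per locus.

    ``loci`` maps locus name -> (allele1, allele2) with integer allele sizes;
    a missing locus is simply absent from the mapping (or None-valued).
    """

    individual_id: str
    session: str
    loci: dict[str, tuple[int, int] | None] = field(repr=False)

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        for locus, pair in self.loci.items():
            if pair is not None and len(pair) != 2:
                raise ValueError(f"locus {locus!r} must carry exactly two alleles")

    @property
    def scored_loci(self) -> set[str]:
        return {k for k, v in self.loci.items() if v is not None}


def allele_distance(
    g1: MultilocusGenotype, g2: MultilocusGenotype, min_shared_loci: int = 10
) -> int | None:
    """Total allele mismatches between two genotypes over co-scored loci.

    Per locus the contribution is the multiset-difference size between the
    unordered allele pairs: 0 (same pair), 1 (one shared allele) or 2.
    Returns None when fewer than ``min_shared_loci`` loci are co-scored
    (comparison invalid).
    """
    shared = g1.scored_loci & g2.scored_loci
    if len(shared) < min_shared_loci:
        return None
    dist = 0
    for locus in shared:
        a = sorted(g1.loci[locus])  # type: ignore[arg-type]
        b = sorted(g2.loci[locus])  # type: ignore[arg-type]
        if a == b:
            continue
        # unordered pairs: one shared allele -> 1 mismatch, none -> 2
        if a[0] in b or a[1] in b:
            # guard double-counting when one pair is homozygous
            common = 0
            bb = list(b)
            for allele in a:
                if allele in bb:
                    bb.remove(allele)
                    common += 1
            dist += 2 - common
        else:
            dist += 2
    return dist


@dataclass(frozen=True)
class MatchReport:
    """Outcome of recapture matching between two sessions."""

    pairs: list[tuple[str, str, int]]  # (spring id, fall id, distance)
    unmatched_spring: list[str]
    unmatched_fall: list[str]
    ambiguous_spring: list[str]
    ambiguous_fall: list[str]

    @property
    def n_recaptured(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["spring_id", "fall_id", "distance"])


def match_recaptures(
    spring: list[MultilocusGenotype],
    fall: list[MultilocusGenotype],
    max_allele_mismatch: int = 1,
    min_shared_loci: int = 10,
) -> MatchReport:
    """Pair spring and fall genotypes identical up to the mismatch tolerance.

    A candidate pair has allele distance <= ``max_allele_mismatch`` over at
    least ``min_shared_loci`` co-scored loci. Genotypes with exactly one
    candidate on both sides are matched; genotypes with several candidates
    are flagged ambiguous and excluded (no arbitrary tie-breaking); the rest
    are reported unmatched (capture failure or mortality candidates).
    """
    for g, expected in [(g, "spring") for g in spring] + [(g, "fall") for g in fall]:
        if not g.scored_loci:
            raise ValueError(f"genotype {g.individual_id!r} has zero scored loci")
        if g.session != expected:
            raise ValueError(
                f"genotype {g.individual_id!r} labelled {g.session!r} in the {expected} set"
            )
    if spring and fall:
        panel = set().union(*(g.loci.keys() for g in spring + fall))
        if not panel:
            raise ValueError("empty locus panel")

    candidates: list[tuple[int, int, int]] = []
    for i, gs in enumerate(spring):
        for j, gf in enumerate(fall):
            d = allele_distance(gs, gf, min_shared_loci)
            if d is not None and d <= max_allele_mismatch:
                candidates.append((i, j, d))

    from collections import Counter

    deg_s = Counter(i for i, _, _ in candidates)
    deg_f = Counter(j for _, j, _ in candidates)
    ambiguous_s = {i for i, c in deg_s.items() if c > 1}
    ambiguous_f = {j for j, c in deg_f.items() if c > 1}
    # a genotype whose only candidate is ambiguous on the other side is also unsafe
    changed = True
    while changed:
        changed = False
        for i, j, _ in candidates:
            if i in ambiguous_s and j not in ambiguous_f and deg_f[j] == 1:
                ambiguous_f.add(j)
                changed = True
            if j in ambiguous_f and i not in ambiguous_s and deg_s[i] == 1:
                ambiguous_s.add(i)
                changed = True

    pairs = [
        (spring[i].individual_id, fall[j].individual_id, d)
        for i, j, d in candidates
        if i not in ambiguous_s and j not in ambiguous_f
    ]
    matched_s = {p[0] for p in pairs}
    matched_f = {p[1] for p in pairs}
    amb_s_ids = sorted(spring[i].individual_id for i in ambiguous_s)
    amb_f_ids = sorted(fall[j].individual_id for j in ambiguous_f)
    unmatched_s = [
        g.individual_id
        for g in spring
        if g.individual_id not in matched_s and g.individual_id not in amb_s_ids
    ]
    unmatched_f = [
        g.individual_id
        for g in fall
        if g.individual_id not in matched_f and g.individual_id not in amb_f_ids
    ]
    return MatchReport(sorted(pairs), unmatched_s, unmatched_f, amb_s_ids, amb_f_ids)


def read_genotypes(path: str | Path, session: str, sep: str = "\t") -> list[MultilocusGenotype]:
    """Read a delimited genotype table: id column then two columns per locus.

    Locus columns are named ``<locus>_1`` and ``<locus>_2``; blank cells mean
    the locus was not scored.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "id" not in frame.columns:
        raise ValueError("genotype table needs an 'id' column")
    locus_names: list[str] = []
    for col in frame.columns:
        if col.endswith("_1"):
            base = col[:-2]
            if f"{base}_2" in frame.columns:
                locus_names.append(base)
    out = []
    for _, row in frame.iterrows():
        loci: dict[str, tuple[int, int] | None] = {}
        for locus in locus_names:
            a1, a2 = row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip()
            loci[locus] = (int(a1), int(a2)) if a1 and a2 else None
        out.append(MultilocusGenotype(str(row["id"]), session, loci))
    return out


def incidence_table(cohort: pd.DataFrame, grouping=("family_id", "environment_id")) -> pd.DataFrame:
    """Counts and percentage of mature males per group.

    Parameters
    ----------
    cohort : DataFrame
        Phenotype records; only male records are counted.
    grouping : str or sequence of str
        Column(s) to group by, e.g. ('family_id', 'environment_id'),
        'sire_type', or any custom column present in the table.

    Returns
    -------
    DataFrame
        Columns n_males, n_mature, incidence_pct (one decimal, NaN +
        ``undefined`` flag for groups with zero males).
    """
    if isinstance(grouping, str):
        grouping = (grouping,)
    males = validate_cohort(cohort)
    for col in grouping:
        if col not in males.columns:
            raise KeyError(f"grouping column {col!r} not in cohort table")
    # observed=False keeps empty categorical groups visible (undefined incidence)
    grouped = males.groupby(list(grouping), sort=True, observed=False)["Y"].agg(["count", "sum"])
    grouped.columns = ["n_males", "n_mature"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * grouped["n_mature"] / grouped["n_males"]
    grouped["incidence_pct"] = pct.where(grouped["n_males"] > 0).round(1)
    grouped["undefined"] = grouped["n_males"] == 0
    return grouped.reset_index()
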