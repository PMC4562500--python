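"""Allele-frequency time-course reconstruction from mixed sequencing calls.

Implements the reconstruction rules used for the evolution experiments:

* per (allele, day), the frequency knot is the mean of the Sanger and
  whole-genome calls when both exist, or the single available call;
* linked alleles (established by co-occurrence in clonal isolates) get a
  whole-genome estimate equal to the mean of their members' calls,
  averaged again with a clone-proportion Sanger estimate when one
  exists at that day;
* the ancestral series is clamped at 0 after it first reaches 0, with
  no renormalization of the mutant series;
* trajectories between knots are drawn with a second-order (quadratic)
  spline, falling back to a line for two knots, clipped to [0, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline

__all__ = [
    "AlleleObservation", "LinkageGroup", "TimeCourse",
    "merge_method_frequencies", "resolve_linkage", "clamp_ancestral",
    "interpolate_trajectory", "linkage_groups_from_clones",
    "sanger_linked_frequencies", "reconstruct_timecourses",
]

METHODS = ("sanger", "wgs")


@dataclass(frozen=True)
class AlleleObservation:
    allele_id: str
    day: float
    method: str
    frequency: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")


@dataclass(frozen=True)
class LinkageGroup:
    """Alleles established as co-occurring in clonal isolates."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a linkage group needs >= 2 members")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.members))


@dataclass
class TimeCourse:
    """Reconstructed trajectory of one allele (or linked group)."""

    allele_id: str
    knot_days: np.ndarray
    knot_freqs: np.ndarray
    grid_days: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_freqs: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_freqs_raw: np.ndarray = field(default_factory=lambda: np.array([]))


def _validate_obs(obs: pd.DataFrame) -> pd.DataFrame:
    required = {"allele_id", "day", "method", "frequency"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    bad = obs[(obs["frequency"] < 0) | (obs["frequency"] > 1)]
    if len(bad):
        raise ValueError(
            "frequencies outside [0, 1] in rows: " + ", ".join(
                f"({r.allele_id}, day {r.day}, {r.method}, {r.frequency})"
                for r in bad.itertuples()))
    bad_m = set(obs["method"]) - set(METHODS)
    if bad_m:
        raise ValueError(f"unknown sequencing methods: {sorted(bad_m)}")
    dup = obs.duplicated(["allele_id", "day", "method"])
    if dup.any():
        raise ValueError("duplicate (allele_id, day, method) observations")
    return obs


def merge_method_frequencies(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-(allele, day) knots: mean of both methods, or the single one.

    Days observed by neither method yield no knot.  Idempotent on its
    own output (re-merging merged knots is a no-op).
    """
    if "method" not in obs.columns and {"allele_id", "day", "frequency"} <= set(obs.columns):
        return obs[["allele_id", "day", "frequency"]].copy()  # already merged
    obs = _validate_obs(obs)
    merged = (obs.groupby(["allele_id", "day"], as_index=False)["frequency"]
                 .mean())
    return merged.sort_values(["allele_id", "day"], ignore_index=True)


def linkage_groups_from_clones(clones: pd.DataFrame) -> list[LinkageGroup]:
    """Infer perfect-linkage groups from a clonal genotype table.

    ``clones`` has columns clone_id, day, allele_id, present (0/1).
    Two alleles are grouped when, across every genotyped clone, each is
    present exactly when the other is (perfect co-occurrence).
    """
    required = {"clone_id", "allele_id", "present"}
    if not required <= set(clones.columns):
        raise ValueError(f"clonal table needs columns {sorted(required)}")
    mat = (clones.pivot_table(index="clone_id", columns="allele_id",
                              values="present", fill_value=0, aggfunc="max"))
    groups: list[set[str]] = []
    alleles = [a for a in mat.columns if mat[a].any()]
    for a in alleles:
        placed = False
        for grp in groups:
            rep = next(iter(grp))
            if (mat[a] == mat[rep]).all():
                grp.add(a)
                placed = True
                break
        if not placed:
            groups.append({a})
    return [LinkageGroup(frozenset(g)) for g in groups if len(g) >= 2]


def sanger_linked_frequencies(clones: pd.DataFrame,
                              group: LinkageGroup) -> pd.DataFrame:
    """Clone-proportion estimate of a linked haplotype's frequency per day.

    The fraction of genotyped clones carrying the full member set
    (simple proportion).
    """
    days = []
    freqs = []
    for day, sub in clones.groupby("day"):
        mat = sub.pivot_table(index="clone_id", columns="allele_id",
                              values="present", fill_value=0, aggfunc="max")
        have = [m for m in group.members if m in mat.columns]
        if len(have) < len(group.members):
            carrier = np.zeros(len(mat), dtype=bool)
        else:
            carrier = (mat[list(group.members)] == 1).all(axis=1).to_numpy()
        days.append(day)
        freqs.append(float(carrier.mean()) if len(carrier) else np.nan)
    return pd.DataFrame({"day": days, "frequency": freqs}).dropna()


def resolve_linkage(knots: pd.DataFrame, groups: list[LinkageGroup],
                    sanger_linked: dict[str, pd.DataFrame] | None = None,
                    wgs_obs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add linked-haplotype knots; unlinked alleles pass through unchanged.

    For each group and day where every member has a whole-genome call,
    the linked estimate is the mean of the member calls (generalized
    from pairs to any group size); where a Sanger clone-proportion
    estimate also exists at that day, the final knot is the mean of the
    two.  Member alleles missing a call at a day raise a warning and
    skip the group at that day.
    """
    sanger_linked = sanger_linked or {}
    source = wgs_obs if wgs_obs is not None else knots
    out = [knots]
    for group in groups:
        rows = []
        member_days = [set(source.loc[source["allele_id"] == m, "day"])
                       for m in group.members]
        all_days = set().union(*member_days)
        common = set.intersection(*member_days) if member_days else set()
        for day in sorted(all_days):
            if day not in common:
                warnings.warn(
                    f"linkage group {group.label}: member missing at day {day}; skipped")
                continue
            vals = [float(source.loc[(source["allele_id"] == m)
                                     & (source["day"] == day), "frequency"].iloc[0])
                    for m in group.members]
            est = float(np.mean(vals))
            sg = sanger_linked.get(group.label)
            if sg is not None and (sg["day"] == day).any():
                s_val = float(sg.loc[sg["day"] == day, "frequency"].iloc[0])
                est = 0.5 * (est + s_val)
            rows.append({"allele_id": group.label, "day": day, "frequency": est})
        if rows:
            out.append(pd.DataFrame(rows))
    return pd.concat(out, ignore_index=True).sort_values(
        ["allele_id", "day"], ignore_index=True)


def clamp_ancestral(series: pd.DataFrame) -> pd.DataFrame:
    """Hold the ancestral series at 0 after its first 0.

    Mutant frequencies are deliberately left unnormalized even if they
    then fail to account for 100%.  Idempotent.
    """
    out = series.sort_values("day", ignore_index=True).copy()
    f = out["frequency"].to_numpy(dtype=float)
    zero = np.nonzero(f <= 0)[0]
    if zero.size:
        f[zero[0]:] = 0.0
    out["frequency"] = f
    return out


def interpolate_trajectory(knot_days, knot_freqs, grid_days=None,
                           points_per_day: int = 4):
    """Quadratic-spline interpolation through the knots, clipped to [0,1].

    Returns (grid_days, clipped, raw).  Two knots fall back to a linear
    segment; a single knot is not interpolable (warning, empty output).
    """
    d = np.asarray(knot_days, dtype=float)
    f = np.asarray(knot_freqs, dtype=float)
    order = np.argsort(d)
    d, f = d[order], f[order]
    if len(d) < 2:
        warnings.warn("fewer than 2 knots: interpolation skipped")
        empty = np.array([])
        return empty, empty, empty
    if grid_days is None:
        grid_days = np.linspace(d[0], d[-1],
                                int(round((d[-1] - d[0]) * points_per_day)) + 1)
    grid_days = np.asarray(grid_days, dtype=float)
    k = min(2, len(d) - 1)
    spl = InterpolatedUnivariateSpline(d, f, k=k)
    raw = spl(grid_days)
    return grid_days, np.clip(raw, 0.0, 1.0), raw


def reconstruct_timecourses(
    obs: pd.DataFrame,
    clones: pd.DataFrame | None = None,
    anchor_day0: bool = True,
    points_per_day: int = 4,
) -> dict[str, TimeCourse]:
    """Full reconstruction: merge, link, clamp, interpolate.

    ``obs`` is the observation table (allele_id, day, method,
    frequency); ``clones`` the clonal genotype table used for linkage.
    Mutant trajectories are anchored at frequency 0 on day 0 unless an
    observation exists there.  The ancestral series (key "ancestral")
    is 1 minus the linked-resolved mutant sum, clamped after its first
    0.
    """
    obs = _validate_obs(obs)
    knots = merge_method_frequencies(obs)
    groups: list[LinkageGroup] = []
    sanger_linked: dict[str, pd.DataFrame] = {}
    if clones is not None and len(clones):
        groups = linkage_groups_from_clones(clones)
        sanger_linked = {g.label: sanger_linked_frequencies(clones, g)
                         for g in groups}
    wgs = obs[obs["method"] == "wgs"]
    knots = resolve_linkage(knots, groups, sanger_linked, wgs_obs=wgs)

    grouped = {m for g in groups for m in g.members}
    courses: dict[str, TimeCourse] = {}
    for allele, sub in knots.groupby("allele_id"):
        d = sub["day"].to_numpy(dtype=float)
        f = sub["frequency"].to_numpy(dtype=float)
        if anchor_day0 and 0.0 not in d:
            d = np.concatenate([[0.0], d])
            f = np.concatenate([[0.0], f])
        grid, clipped, raw = interpolate_trajectory(
            d, f, points_per_day=points_per_day) if len(d) >= 2 else (
            np.array([]), np.array([]), np.array([]))
        courses[allele] = TimeCourse(allele_id=allele, knot_days=d,
                                     knot_freqs=f, grid_days=grid,
                                     grid_freqs=clipped, grid_freqs_raw=raw)

    # ancestral series: 1 - sum of mutant knots, linked members counted once
    top_level = [a for a in courses if a not in grouped]
    days = sorted({float(day) for a in top_level for day in courses[a].knot_days})
    anc_rows = []
    for day in days:
        total = 0.0
        for a in top_level:
            tc = courses[a]
            m = tc.knot_days == day
            if m.any():
                total += float(tc.knot_freqs[m][0])
        anc_rows.append({"day": day, "frequency": max(0.0, 1.0 - total)})
    anc = clamp_ancestral(pd.DataFrame(anc_rows)) if anc_rows else \
        pd.DataFrame(columns=["day", "frequency"])
    if len(anc) >= 2:
        grid, clipped, raw = interpolate_trajectory(
            anc["day"], anc["frequency"], points_per_day=points_per_day)
    else:
        grid = clipped = raw = np.array([])
    courses["ancestral"] = TimeCourse(
        allele_id="ancestral",
        knot_days=anc["day"].to_numpy(dtype=float),
        knot_freqs=anc["frequency"].to_numpy(dtype=float),
        grid_days=grid, grid_freqs=clipped, grid_freqs_raw=raw)
    return courses


def timecourses_to_frame(courses: dict[str, TimeCourse]) -> pd.DataFrame:
    """Tidy export: (allele_id, day, frequency, source in {knot, interpolated})."""
    rows = []
    for tc in courses.values():
        for d, f in zip(tc.knot_days, tc.knot_freqs):
            rows.append((tc.allele_id, float(d), float(f), "knot"))
        for d, f in zip(tc.grid_days, tc.grid_freqs):
            rows.append((tc.allele_id, float(d), float(f), "interpolated"))
    return pd.DataFrame(rows, columns=["allele_id", "day", "frequency", "source"])
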