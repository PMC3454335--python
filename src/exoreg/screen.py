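"""Staged reporter-screen workflow: normalize, select, confirm, classify.

The workflow takes plate tables of dual-reporter wells through:

1. log10 firefly/Renilla relative activity,
2. quantile normalization across plates, separately per digestion enzyme
   (controls excluded from the reference set but mapped through it),
3. two-standard-deviation candidate selection (both tails),
4. optional exonic-alignment filtering,
5. two confirmation rounds (3 then 8 replicates) of one-sample t tests
   against the promoter-only reference, each gated at BH FDR < 5%, with
   the effect sign required to agree across rounds,
6. enhancer/silencer classification by the sign of the confirmed effect.

Stage outputs are nested subsets: confirmed <= round1-pass <= selected
<= screened.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CloneMeasurement, DataError
from .stats import QuantileNormalizer, TestResult, bh_fdr, one_sample_t

__all__ = [
    "relative_activity",
    "to_activity_table",
    "normalize_screen",
    "select_candidates",
    "confirm_rounds",
    "classify_call",
    "run_screen",
    "ScreenCall",
    "ScreenOptions",
]


def relative_activity(firefly: float, renilla: float) -> float:
    """log10 ratio of firefly to Renilla signal."""
    if firefly <= 0 or renilla <= 0:
        raise DataError("relative activity requires positive signals")
    return math.log10(firefly / renilla)


def to_activity_table(measurements) -> pd.DataFrame:
    """Tabulate usable wells with their relative activities.

    Accepts CloneMeasurement collections or a raw plate DataFrame.
    Unusable wells (non-positive signals) are excluded here — they were
    flagged at parse time and carry no ratio.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = [
            CloneMeasurement(str(r.clone_id), str(r.batch_id), str(r.enzyme),
                             str(r.well_role), float(r.firefly), float(r.renilla))
            for r in measurements.itertuples(index=False)
        ]
    rows = [
        {
            "clone_id": m.clone_id,
            "batch_id": m.batch_id,
            "enzyme": m.enzyme,
            "well_role": m.well_role,
            "relative_activity": relative_activity(m.firefly, m.renilla),
        }
        for m in measurements
        if m.usable
    ]
    return pd.DataFrame(rows)


def normalize_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize activities across plates within each enzyme group.

    The normalization reference set is the experimental wells of each
    (enzyme, batch); control wells are mapped through their plate's fitted
    quantile map. An enzyme group with a single batch passes through
    unchanged with a warning. Control wells are assigned to the enzyme
    group of the experimental wells sharing their plate.
    """
    df = table.copy()
    df["normalized_activity"] = df["relative_activity"].astype(float)
    exp = df[df["well_role"] == "experimental"]
    batch_enzyme = exp.groupby("batch_id")["enzyme"].agg(
        lambda s: s.mode().iat[0])
    for enzyme, grp in exp.groupby("enzyme"):
        batches = {b: g["relative_activity"].to_numpy()
                   for b, g in grp.groupby("batch_id")}
        if len(batches) < 2:
            warnings.warn(
                f"enzyme group {enzyme!r} has a single batch; "
                "normalization is a pass-through")
            continue
        qn = QuantileNormalizer().fit(batches)
        for b, g in grp.groupby("batch_id"):
            df.loc[g.index, "normalized_activity"] = qn.normalize(
                b, g["relative_activity"].to_numpy())
        ctrl = df[(df["well_role"] != "experimental")
                  & df["batch_id"].map(batch_enzyme).eq(enzyme)]
        for b, g in ctrl.groupby("batch_id"):
            if b in qn.batch_sorted_:
                df.loc[g.index, "normalized_activity"] = qn.transform_through(
                    b, g["relative_activity"].to_numpy())
    return df


def select_candidates(table: pd.DataFrame, n_sd: float = 2.0) -> set[str]:
    """Clones whose normalized activity is beyond mean +/- n_sd * sd.

    The mean and sample sd are computed over experimental clones only,
    per enzyme group; both tails are selected.
    """
    col = ("normalized_activity" if "normalized_activity" in table.columns
           else "relative_activity")
    exp = table[table["well_role"] == "experimental"]
    if len(exp) < 3:
        raise DataError("candidate selection requires >= 3 experimental clones")
    selected: set[str] = set()
    for enzyme, grp in exp.groupby("enzyme"):
        vals = grp[col].to_numpy()
        sd = vals.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"enzyme group {enzyme!r} has zero spread; "
                          "no candidates selected")
            continue
        mean = vals.mean()
        hit = np.abs(vals - mean) > n_sd * sd
        selected.update(grp["clone_id"].to_numpy()[hit])
    return selected


@dataclass
class ScreenCall:
    clone_id: str
    call: str  # enhancer | silencer | not_confirmed
    round1: TestResult | None = None
    round2: TestResult | None = None
    q1: float | None = None
    q2: float | None = None
    mean_activity: float | None = None
    notes: list[str] = field(default_factory=list)


def _round_activities(round_table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    acts = to_activity_table(round_table)
    ref_rows = acts[acts["well_role"] == "promoter_only"]
    if ref_rows.empty:
        raise DataError("confirmation round has no promoter-only reference wells")
    return acts, float(ref_rows["relative_activity"].mean())


def confirm_rounds(candidates, round1: pd.DataFrame, round2: pd.DataFrame,
                   fdr: float = 0.05) -> dict[str, ScreenCall]:
    """Two-round confirmation against the promoter-only reference.

    Per round, each candidate's replicate activities are tested with a
    one-sample t against the round's reference (mean promoter-only
    activity); BH correction is applied across candidates within the
    round. A clone is confirmed only when q < ``fdr`` in BOTH rounds with
    the same effect sign; round 2 is only run for round-1 passers.
    """
    candidates = sorted(candidates)
    calls = {c: ScreenCall(clone_id=c, call="not_confirmed") for c in candidates}
    if not candidates:
        return calls

    def run_round(round_table, subset, slot):
        acts, ref = _round_activities(round_table)
        results, tested = [], []
        for cid in subset:
            vals = acts.loc[(acts["clone_id"] == cid)
                            & (acts["well_role"] == "experimental"),
                            "relative_activity"].to_numpy()
            if vals.size < 2:
                calls[cid].notes.append(f"{slot}: <2 usable replicates")
                continue
            res = one_sample_t(vals, ref)
            setattr(calls[cid], slot, res)
            calls[cid].mean_activity = float(vals.mean())
            if not res.ok:
                calls[cid].notes.append(f"{slot}: {res.flag}")
                continue
            results.append(res)
            tested.append(cid)
        if not tested:
            return [], ref
        qs = bh_fdr([r.p_value for r in results])
        passers = []
        for cid, res, q in zip(tested, results, qs):
            setattr(calls[cid], "q1" if slot == "round1" else "q2", float(q))
            if q < fdr:
                passers.append((cid, math.copysign(1.0, res.statistic)))
        return passers, ref

    round1_pass, _ = run_round(round1, candidates, "round1")
    if not round1_pass:
        return calls
    round2_pass, ref2 = run_round(round2, [c for c, _ in round1_pass], "round2")
    signs1 = dict(round1_pass)
    for cid, sign2 in round2_pass:
        if signs1[cid] != sign2:
            calls[cid].notes.append("sign flip between rounds")
            continue
        calls[cid].call = classify_call(calls[cid].mean_activity, ref2)
    return calls


def classify_call(confirmed_mean: float, reference: float) -> str:
    """Enhancer when the confirmed mean exceeds the reference, else silencer."""
    return "enhancer" if confirmed_mean > reference else "silencer"


@dataclass
class ScreenOptions:
    n_sd: float = 2.0
    fdr: float = 0.05
    use_normalized: bool = True
    min_identity: float = 0.98


def run_screen(plates: pd.DataFrame, round1: pd.DataFrame, round2: pd.DataFrame,
               options: ScreenOptions | None = None, alignments=None,
               genes=None) -> tuple[dict[str, ScreenCall], dict]:
    """Full screening workflow; returns calls and a stage-count report.

    ``alignments``/``genes`` optionally restrict candidates to clones
    whose best alignment lands in an exon (see
    :func:`exoreg.context.filter_exonic_clones`); when omitted that stage
    is an identity.
    """
    opts = options or ScreenOptions()
    table = to_activity_table(plates)
    if opts.use_normalized:
        table = normalize_screen(table)
    selected = select_candidates(table, n_sd=opts.n_sd)
    if alignments is not None and genes is not None:
        from .context import filter_exonic_clones

        retained, _ = filter_exonic_clones(alignments, genes,
                                           min_identity=opts.min_identity)
        exon_retained = selected & retained
    else:
        exon_retained = selected
    calls = confirm_rounds(exon_retained, round1, round2, fdr=opts.fdr)
    round1_pass = {c for c, call in calls.items()
                   if call.q1 is not None and call.q1 < opts.fdr}
    confirmed = {c for c, call in calls.items() if call.call != "not_confirmed"}
    report = {
        "screened": int(table.loc[table["well_role"] == "experimental",
                                  "clone_id"].nunique()),
        "selected": len(selected),
        "exon_retained": len(exon_retained),
        "round1_pass": len(round1_pass),
        "round2_pass": len(confirmed),
        "enhancers": sum(1 for c in confirmed if calls[c].call == "enhancer"),
        "silencers": sum(1 for c in confirmed if calls[c].call == "silencer"),
    }
    return calls, report
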