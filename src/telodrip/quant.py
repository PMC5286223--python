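"""DRIP-qPCR and qRT-PCR quantification.

Turns long-format Ct tables into the quantities the analysis reports:

* percent-of-input DRIP enrichment, ``2**(Ct_1%input - Ct_IP)`` — a value of
  1 means the immunoprecipitate recovered as much template as the reserved
  1% input aliquot.  The formula is applied literally; an optional
  ``dilution_correction`` multiplies by 1/100 for absolute-fraction
  reporting (it cancels in every ratio, default off).
* relative enrichment against a declared baseline stratum (the -HinfI
  fraction set at 1; the G1 cell-cycle fraction set at 1).
* RNase H specificity ratios (treated / untreated signal).
* ddCt relative expression with a reference gene and a calibrator sample.

Replicates are aggregated by geometric mean on the linear scale
(equivalently, arithmetic mean of Ct differences): qPCR noise is additive
in cycles, hence log-normal in linear signal.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

STRATA = ["sample", "group", "locus", "treatment", "phase"]


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct/enrichment CSV keeping the literal phase token "NA"
    (pandas would otherwise coerce it to missing)."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def percent_input(ct_input_1pct, ct_ip, dilution_correction: bool = False):
    """Percent-of-input recovery from paired Ct values.

    Accepts scalars or aligned arrays.  Equal Cts give 1.0; each extra IP
    cycle halves the value.
    """
    a = np.asarray(ct_input_1pct, dtype=float)
    b = np.asarray(ct_ip, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("Ct values must be finite")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("Ct values must be > 0")
    out = np.power(2.0, a - b)
    if dilution_correction:
        out = out / 100.0
    return out.item() if out.ndim == 0 else out


def percent_input_table(ct_table: pd.DataFrame,
                        dilution_correction: bool = False) -> pd.DataFrame:
    """Pair IP rows with their 1%-input partners and compute percent input.

    Partner matching is by (sample, locus, treatment, phase); replicates are
    aggregated by mean Ct within each stratum before pairing.  An IP stratum
    with no input partner raises, naming the orphan key.
    """
    required = {"sample", "group", "locus", "fraction", "treatment",
                "phase", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    mean_ct = (ct_table
               .groupby(STRATA + ["fraction"], as_index=False, sort=False)
               ["ct"].mean())
    wide = mean_ct.pivot_table(index=STRATA, columns="fraction", values="ct",
                               sort=False)
    for col in ("IP", "input_1pct"):
        if col not in wide.columns:
            raise ValueError(f"Ct table has no {col!r} rows")
    orphans = wide.index[wide["input_1pct"].isna() & wide["IP"].notna()]
    if len(orphans):
        raise ValueError(
            f"IP rows without matching input_1pct partner: {list(orphans)}")
    wide = wide.dropna(subset=["IP"])
    out = wide.reset_index()
    out["percent_input"] = percent_input(
        out["input_1pct"].to_numpy(), out["IP"].to_numpy(),
        dilution_correction=dilution_correction)
    return out[STRATA + ["percent_input"]]


def relative_enrichment(table: pd.DataFrame, baseline_col: str,
                        baseline_value: str,
                        strata: Sequence[str] = ("sample", "locus")
                        ) -> pd.DataFrame:
    """Express percent-input values relative to a baseline condition.

    Within each stratum (default: per sample per locus) the row whose
    *baseline_col* equals *baseline_value* is set to exactly 1 and the
    others are divided by its percent input — e.g. the -HinfI fraction, or
    the G1 cell-cycle fraction, arbitrarily set at 1.  Strata lacking a
    baseline row (or with zero baseline) are dropped with a warning.
    """
    if "percent_input" not in table.columns:
        raise ValueError("expected an enrichment table with percent_input")
    parts = []
    for key, grp in table.groupby(list(strata), sort=False):
        base = grp.loc[grp[baseline_col] == baseline_value, "percent_input"]
        if base.empty or not np.all(base > 0):
            warnings.warn(f"stratum {key}: missing or zero baseline "
                          f"({baseline_col}={baseline_value}); dropped",
                          stacklevel=2)
            continue
        g = grp.copy()
        g["relative"] = g["percent_input"] / base.mean()
        g.loc[g[baseline_col] == baseline_value, "relative"] = 1.0
        parts.append(g)
    if not parts:
        raise ValueError("no stratum had a usable baseline")
    return pd.concat(parts, ignore_index=True)


def rnaseh_reduction(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treated/untreated signal ratio per sample x locus, plus a per-locus
    mean +/- s.e.m. summary.  Raises on unpaired rows."""
    if "percent_input" not in table.columns:
        raise ValueError("expected an enrichment table with percent_input")
    sub = table
    if "phase" in table.columns:
        sub = table[table["phase"] == "NA"]
    wide = sub.pivot_table(index=["sample", "group", "locus"],
                           columns="treatment", values="percent_input",
                           sort=False)
    for col in ("none", "rnaseh"):
        if col not in wide.columns:
            raise ValueError(f"no {col!r} treatment rows present")
    unpaired = wide.index[wide[["none", "rnaseh"]].isna().any(axis=1)]
    if len(unpaired):
        raise ValueError(f"unpaired +/-RNase H rows at: {list(unpaired)}")
    per = wide.reset_index()
    per["ratio"] = per["rnaseh"] / per["none"]
    summary = (per.groupby("locus", sort=False)["ratio"]
               .agg(mean="mean", sem=lambda x: x.sem(), n="count")
               .reset_index())
    return per[["sample", "group", "locus", "ratio"]], summary


def ddct_expression(ct_table: pd.DataFrame,
                    reference_locus: str,
                    calibrator: Mapping[str, str],
                    strata: Sequence[str] = ("sample", "phase")
                    ) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    dCt = Ct_target - Ct_reference within each stratum; ddCt subtracts the
    per-locus dCt of the calibrator stratum (e.g. the G1 fraction of sample
    WT1, set at 1); expression = 2**(-ddCt).  Replicate Cts are averaged
    before differencing.
    """
    required = {"sample", "locus", "phase", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    strata = list(strata)
    mean_ct = (ct_table.groupby(strata + ["locus"], as_index=False,
                                sort=False)["ct"].mean())
    ref = mean_ct[mean_ct["locus"] == reference_locus] \
        .set_index(strata)["ct"]
    tgt = mean_ct[mean_ct["locus"] != reference_locus]
    if tgt.empty:
        raise ValueError("no target rows (everything is the reference locus)")
    keys = pd.MultiIndex.from_frame(tgt[strata])
    if not keys.isin(ref.index).all():
        orphan = keys[~keys.isin(ref.index)].unique().tolist()
        raise ValueError(f"missing reference rows for strata: {orphan}")
    out = tgt.copy()
    out["dct"] = tgt["ct"].to_numpy() - ref.loc[keys].to_numpy()

    cal_mask = np.ones(len(out), dtype=bool)
    for col, val in calibrator.items():
        cal_mask &= (out[col] == val).to_numpy()
    cal = out[cal_mask].set_index("locus")["dct"]
    if cal.empty:
        raise ValueError(f"calibrator stratum {dict(calibrator)} not found")
    loci = out["locus"]
    if not loci.isin(cal.index).all():
        raise ValueError("calibrator stratum lacks some target loci")
    out["ddct"] = out["dct"].to_numpy() - cal.loc[loci].to_numpy()
    out["expression"] = np.power(2.0, -out["ddct"])
    return out[strata + ["locus", "dct", "ddct", "expression"]]


def group_summary(table: pd.DataFrame, value: str = "percent_input",
                  by: Sequence[str] = ("group", "locus")) -> pd.DataFrame:
    """Mean, geometric mean, s.e.m. and n of *value* per group x locus."""
    def gmean(x):
        return float(np.exp(np.mean(np.log(x))))

    return (table.groupby(list(by), sort=False)[value]
            .agg(mean="mean", gmean=gmean, sem=lambda x: x.sem(), n="count")
            .reset_index())
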