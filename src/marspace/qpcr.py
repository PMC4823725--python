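"""ΔΔCt quantification for ChIP-qPCR and RT-qPCR.

ChIP enrichment over the IgG mock-immunoprecipitation control:

    ΔΔCt(ChIP − IgG) = (mean Ct_ChIP − mean Ct_input) − (mean Ct_IgG − mean Ct_input)
    Fold change      = 2^(−ΔΔCt)

Relative expression normalizes a target gene to a reference gene (GAPDH)
and a control condition the same way. Means are arithmetic means of Ct in
cycles; amplification efficiency is assumed to be exactly 2 per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataError

__all__ = ["CtTable", "EnrichmentResult", "chip_fold_enrichment", "rt_relative_expression"]

ROLES = ("chip", "igg", "input", "target", "reference")


@dataclass(frozen=True)
class EnrichmentResult:
    ddct: float
    fold_change: float
    n_replicates: dict
    role_means: dict

    def to_dict(self) -> dict:
        return {
            "ddct": self.ddct,
            "fold_change": self.fold_change,
            "n_replicates": dict(self.n_replicates),
            "role_means": dict(self.role_means),
        }


class CtTable:
    """Replicate threshold-cycle measurements.

    Wraps a DataFrame with columns role, condition, replicate, ct. Ct values
    must be finite and positive.
    """

    COLUMNS = ("role", "condition", "replicate", "ct")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"Ct table missing columns: {missing}")
        df = df.copy()
        df["role"] = df["role"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["ct"] = pd.to_numeric(df["ct"])
        bad = df["role"][~df["role"].isin(ROLES)].unique().tolist()
        if bad:
            raise DataError(f"unknown sample roles: {bad}")
        if not ((df["ct"] > 0) & df["ct"].notna() & (df["ct"] < float("inf"))).all():
            raise DataError("Ct values must be finite and > 0")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int, float]]) -> "CtTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CtTable":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.df.to_csv(path, sep=sep, index=False)

    def role_mean(self, role: str, condition: str | None = None) -> float:
        sub = self.df[self.df["role"] == role]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        if sub.empty:
            where = f" in condition {condition!r}" if condition else ""
            raise DataError(f"no Ct replicates for role {role!r}{where}")
        return float(sub["ct"].mean())

    def role_n(self, role: str, condition: str | None = None) -> int:
        sub = self.df[self.df["role"] == role]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        return int(len(sub))


def chip_fold_enrichment(t: CtTable, condition: str | None = None) -> EnrichmentResult:
    """Fold enrichment of the ChIP sample over the IgG control.

    Requires >= 1 replicate for each of the chip, igg and input roles
    (optionally restricted to one condition).
    """
    means = {role: t.role_mean(role, condition) for role in ("chip", "igg", "input")}
    ddct = (means["chip"] - means["input"]) - (means["igg"] - means["input"])
    return EnrichmentResult(
        ddct=ddct,
        fold_change=2.0 ** (-ddct),
        n_replicates={r: t.role_n(r, condition) for r in ("chip", "igg", "input")},
        role_means=means,
    )


def rt_relative_expression(t: CtTable, treated: str, control: str) -> EnrichmentResult:
    """Relative expression of target vs reference, treated vs control (2^-ΔΔCt)."""
    means = {
        (role, cond): t.role_mean(role, cond)
        for role in ("target", "reference")
        for cond in (treated, control)
    }
    dct_treated = means[("target", treated)] - means[("reference", treated)]
    dct_control = means[("target", control)] - means[("reference", control)]
    ddct = dct_treated - dct_control
    return EnrichmentResult(
        ddct=ddct,
        fold_change=2.0 ** (-ddct),
        n_replicates={
            f"{role}:{cond}": t.role_n(role, cond)
            for role in ("target", "reference")
            for cond in (treated, control)
        },
        role_means={f"{role}:{cond}": v for (role, cond), v in means.items()},
    )
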