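"""Dual-endpoint stable-carbon-isotope mixing model.

Converts enamel-equivalent δ13C values (‰ VPDB) into dietary C4 (grass)
fractions. In lowland tropical Africa nearly all grasses fix carbon via the
C4 pathway while trees, shrubs and forbs are C3, so the C4 fraction of an
herbivore's diet is recoverable from a two-endmember linear mixing model:

    δ13C_measured − ε = δ13C_C3 · f_C3 + δ13C_C4 · f_C4,   f_C3 + f_C4 = 1

where ε is the diet-to-enamel enrichment factor. Default endmembers are the
mean values for tropical African plant biomass (−26.6‰ for C3, −10.0‰ for
C4) and ε = +14.1‰, giving enamel-equivalent endpoints of −12.5‰ and 4.1‰.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixingConfig",
    "GrassFraction",
    "enamel_endpoint",
    "fraction_c4",
    "delta_from_fraction",
    "read_samples",
]

logger = logging.getLogger(__name__)

#: Unicode minus sign occasionally found in exported isotope tables.
_UNICODE_MINUS = "−"


@dataclass(frozen=True)
class MixingConfig:
    """Endmember configuration for the dual-endpoint mixing model.

    Parameters
    ----------
    delta_c3_diet, delta_c4_diet : float
        δ13C (‰ VPDB) of pure C3 / C4 plant biomass. The C4 value must
        exceed the C3 value.
    epsilon : float
        Additive diet-to-enamel enrichment (‰).
    clamp : bool
        If True, fractions falling outside [0, 1] (samples isotopically
        beyond an endmember) are clamped to the nearer bound and flagged.
    """

    delta_c3_diet: float = -26.6
    delta_c4_diet: float = -10.0
    epsilon: float = 14.1
    clamp: bool = True

    def __post_init__(self) -> None:
        for name in ("delta_c3_diet", "delta_c4_diet", "epsilon"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.delta_c4_diet > self.delta_c3_diet:
            raise ValueError(
                "delta_c4_diet must exceed delta_c3_diet "
                f"(got {self.delta_c4_diet} <= {self.delta_c3_diet})"
            )

    @property
    def enamel_c3(self) -> float:
        """Enamel-equivalent C3 endpoint (‰)."""
        return enamel_endpoint(self.delta_c3_diet, self.epsilon)

    @property
    def enamel_c4(self) -> float:
        """Enamel-equivalent C4 endpoint (‰)."""
        return enamel_endpoint(self.delta_c4_diet, self.epsilon)


@dataclass(frozen=True)
class GrassFraction:
    """A C4/C3 dietary split; fractions sum to one exactly."""

    f_c4: float
    clamped: bool = False
    raw: float | None = None

    @property
    def f_c3(self) -> float:
        return 1.0 - self.f_c4


def enamel_endpoint(delta_diet: float, epsilon: float) -> float:
    """Enamel-equivalent δ13C of a diet endmember: ``delta_diet + epsilon``."""
    if not (math.isfinite(delta_diet) and math.isfinite(epsilon)):
        raise ValueError("enamel_endpoint requires finite inputs")
    return delta_diet + epsilon


def fraction_c4(delta13c_enamel, config: MixingConfig | None = None):
    """Dietary grass (C4) fraction from an enamel-equivalent δ13C value.

    Inverts the mixing model:  f_C4 = (δ − e3) / (e4 − e3)  with e3, e4 the
    enamel-equivalent endpoints. Scalar input returns a :class:`GrassFraction`;
    array input returns ``(fractions, clamped_mask)`` as ndarrays.
    """
    config = config or MixingConfig()
    e3, e4 = config.enamel_c3, config.enamel_c4
    if e4 == e3:
        raise ValueError("degenerate endmembers: enamel endpoints coincide")

    scalar = np.isscalar(delta13c_enamel)
    delta = np.asarray(delta13c_enamel, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta13c_enamel must be finite")

    raw = (delta - e3) / (e4 - e3)
    out_of_range = (raw < 0.0) | (raw > 1.0)
    if config.clamp:
        f = np.clip(raw, 0.0, 1.0)
        if np.any(out_of_range):
            logger.warning(
                "%d of %d sample(s) outside endmember range were clamped to [0, 1]",
                int(out_of_range.sum()),
                raw.size,
            )
    else:
        f = raw

    if scalar:
        flag = bool(out_of_range)
        return GrassFraction(float(f), clamped=flag and config.clamp, raw=float(raw))
    return f, out_of_range


def delta_from_fraction(f_c4, config: MixingConfig | None = None):
    """Enamel-equivalent δ13C corresponding to a dietary grass fraction.

    Exact inverse of :func:`fraction_c4` on [0, 1]; used by the synthetic-data
    generator to turn simulated diets back into isotope measurements.
    """
    config = config or MixingConfig()
    f = np.asarray(f_c4, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)) or not np.all(np.isfinite(f)):
        raise ValueError("f_c4 must lie in [0, 1]")
    e3, e4 = config.enamel_c3, config.enamel_c4
    delta = e3 + f * (e4 - e3)
    return float(delta) if np.isscalar(f_c4) else delta


def read_samples(path) -> pd.DataFrame:
    """Read an isotope-sample CSV.

    Expects columns ``sample_id, species, community, d13C_enamel``; accepts
    the Unicode minus (U+2212) alongside the ASCII hyphen-minus in the δ13C
    column. Raises ``ValueError`` naming the offending rows on non-numeric
    or non-finite values and on empty species/community fields.
    """
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    required = ["sample_id", "species", "community", "d13C_enamel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"samples CSV {path} missing column(s): {missing}")

    raw = df["d13C_enamel"].astype(str).str.strip().str.replace(_UNICODE_MINUS, "-", regex=False)
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.index[~np.isfinite(values.to_numpy(dtype=float))]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # 1-based + header line
        raise ValueError(f"non-numeric d13C_enamel in {path} at row(s) {rows}")
    df["d13C_enamel"] = values.astype(float)

    for col in ("species", "community"):
        df[col] = df[col].astype(str).str.strip()
        empty = df.index[(df[col] == "") | (df[col].str.lower() == "nan")]
        if len(empty):
            rows = ", ".join(str(i + 2) for i in empty[:10])
            raise ValueError(f"empty {col} in {path} at row(s) {rows}")
    return df[required]
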