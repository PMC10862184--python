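"""Shared helpers: provenance headers, seeding, rounding."""

from __future__ import annotations

import decimal
import hashlib
import logging
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger("ecoassembly")

PROVENANCE_PREFIX = "# "

from . import __version__ as _pkg_version  # noqa: E402  (circular-safe: set in __init__)


def provenance_lines(seed: int | None = None, **extra: object) -> list[str]:
    """Comment lines recording pipeline version, config hash and seed.

    Lines start with ``"# "`` (hash + space) so that a leading ``#OTU ID``
    header cell is never mistaken for provenance.
    """
    fields: dict[str, object] = {"ecoassembly_version": _pkg_version}
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    digest = hashlib.sha256(repr(sorted(fields.items())).encode()).hexdigest()[:12]
    fields["config_hash"] = digest
    return [f"{PROVENANCE_PREFIX}{k}={v}" for k, v in fields.items()]


def write_tsv_with_provenance(path, frame, seed=None, index_label=None, **extra) -> None:
    import pandas as pd  # local: keep _util import-light

    assert isinstance(frame, pd.DataFrame)
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, **extra):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index_label=index_label)


def strip_provenance(lines: Iterable[str]) -> list[str]:
    """Drop leading ``"# "`` comment lines (provenance), keep everything else."""
    out, body = [], False
    for line in lines:
        if not body and line.startswith(PROVENANCE_PREFIX):
            continue
        body = True
        out.append(line)
    return out


def spawn_seed(master_seed: int, *key: int) -> int:
    """Derive a reproducible 31-bit child seed from a master seed and indices."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention used for printed percentages)."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def format_percent(x: float) -> float:
    """Percentages print with 1 decimal, or 2 decimals when below 1%."""
    return round_half_up(x, 2 if x < 1.0 else 1)


def check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
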