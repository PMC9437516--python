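"""FDA-recommended deduplication of case versions.

FAERS distributes every revision of a case as a separate report version
(PRIMARYID) under a stable CASEID.  The FDA's recommended rule keeps, per
CASEID, the version with the latest FDA receipt date (FDA_DT), breaking
ties by the numerically higher PRIMARYID.  An undated version sorts below
any dated version of the same case and survives only if every version is
undated.

Deduplication is applied to the pooled multi-quarter corpus because case
versions routinely span quarters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from .faers_io import CaseReport

logger = logging.getLogger(__name__)

_DIGITS = re.compile(r"\D+")


@dataclass(frozen=True)
class DedupStats:
    n_input: int
    n_output: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_output


def primaryid_sort_key(primaryid: str) -> tuple[int, str]:
    """Numeric ordering of PRIMARYIDs ('higher PRIMARYID' is numeric).

    Non-digits are stripped before comparison; equal numeric values fall
    back to lexicographic order so the ordering is total.
    """
    digits = _DIGITS.sub("", primaryid)
    return (int(digits) if digits else -1, primaryid)


def _version_key(report: CaseReport) -> tuple[tuple[int, int, int], tuple[int, str]]:
    fda_key = report.fda_dt.sort_key() if report.fda_dt is not None else (0, 0, 0)
    return (fda_key, primaryid_sort_key(report.primaryid))


def deduplicate(reports: Iterable[CaseReport]) -> tuple[list[CaseReport], DedupStats]:
    """Collapse report versions to one report per CASEID.

    Returns the survivors sorted by CASEID (deterministic, independent of
    input order) together with the removal bookkeeping.
    """
    reports = list(reports)
    best: dict[str, CaseReport] = {}
    for report in reports:
        incumbent = best.get(report.caseid)
        if incumbent is None or _version_key(report) > _version_key(incumbent):
            best[report.caseid] = report
    survivors = [best[caseid] for caseid in sorted(best)]
    stats = DedupStats(n_input=len(reports), n_output=len(survivors))
    logger.info("dedup: %d -> %d reports (%d removed)", stats.n_input, stats.n_output, stats.n_removed)
    return survivors, stats
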