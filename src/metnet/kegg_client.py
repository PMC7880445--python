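"""Optional live retrieval from the KEGG REST service, with local caching.

Everything downstream consumes only the on-disk cache, so this module
is never required once KGML files are present: a mocked transport (any
callable ``url -> bytes``) exercises it fully offline. Absence of a
pathway in an organism is a normal outcome in KEGG — the KGML endpoint
has nothing to return — and is cached as a ``.absent`` marker file so
repeated syncs are idempotent without network access.

Cache layout: ``<cache_dir>/<org>/<org><number>.xml`` for downloaded
files, ``<org><number>.absent`` markers for confirmed absences, and
``organisms.tsv`` for the organism list.
"""

from __future__ import annotations

import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from .ids import validate_pathway_number

logger = logging.getLogger(__name__)

__all__ = [
    "KEGG_BASE_URL",
    "OrganismEntry",
    "RetrievalError",
    "FormatError",
    "KeggClient",
]

KEGG_BASE_URL = "https://rest.kegg.jp"

Transport = Callable[[str], bytes]


class RetrievalError(RuntimeError):
    """Transport-level failure talking to the KEGG service."""


class FormatError(ValueError):
    """A response or cached file that cannot be parsed."""


@dataclass(frozen=True)
class OrganismEntry:
    code: str
    name: str
    lineage: str


class _AbsentPathway(Exception):
    """KEGG reports no such pathway for the organism (HTTP 404/empty)."""


def _default_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=30) as response:
            return response.read()
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise _AbsentPathway(url) from exc
        raise RetrievalError(f"HTTP {exc.code} fetching {url}") from exc
    except urllib.error.URLError as exc:
        raise RetrievalError(f"cannot reach {url}: {exc.reason}") from exc


class KeggClient:
    """Cached KEGG REST access.

    Parameters
    ----------
    cache_dir
        Root of the on-disk cache.
    transport
        ``url -> bytes`` callable; raises :class:`RetrievalError` on
        transport failure. Injectable for offline testing.
    delay
        Seconds slept between consecutive requests (politeness; KEGG
        is a shared public service).
    retries
        Attempts per request before giving up.
    """

    def __init__(
        self,
        cache_dir: Path | str,
        transport: Optional[Transport] = None,
        delay: float = 0.35,
        retries: int = 3,
    ) -> None:
        self.cache_dir = Path(cache_dir)
        self.transport = transport or _default_transport
        self.delay = delay
        self.retries = retries
        self._last_request = 0.0

    # -- low level ---------------------------------------------------------

    def _get(self, url: str) -> bytes:
        wait = self._last_request + self.delay - time.monotonic()
        if wait > 0:
            time.sleep(wait)
        last_error: Exception | None = None
        for attempt in range(1, self.retries + 1):
            try:
                self._last_request = time.monotonic()
                logger.info("GET %s (attempt %d)", url, attempt)
                return self.transport(url)
            except _AbsentPathway:
                raise
            except RetrievalError as exc:
                last_error = exc
        raise RetrievalError(
            f"giving up on {url} after {self.retries} attempts: {last_error}"
        )

    # -- organism list -----------------------------------------------------

    def fetch_organism_list(self, refresh: bool = False) -> list[OrganismEntry]:
        """Organism catalogue, from cache when available.

        The live response (``list/organism``) is tab-separated with
        columns T-number, code, name, lineage; it is persisted to the
        cache so later runs work offline.
        """
        cache_file = self.cache_dir / "organisms.tsv"
        if cache_file.exists() and not refresh:
            return self._parse_organism_list(cache_file.read_text(), str(cache_file))
        body = self._get(f"{KEGG_BASE_URL}/list/organism")
        text = body.decode("utf-8")
        entries = self._parse_organism_list(text, "list/organism response")
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(text)
        return entries

    @staticmethod
    def _parse_organism_list(text: str, source: str) -> list[OrganismEntry]:
        entries = []
        for line in text.splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4 or not fields[1]:
                raise FormatError(f"unparseable organism line in {source}: {line!r}")
            entries.append(
                OrganismEntry(code=fields[1], name=fields[2], lineage=fields[3])
            )
        if not entries:
            raise FormatError(f"empty organism list in {source}")
        return entries

    # -- KGML sync ---------------------------------------------------------

    def sync_organism(
        self,
        code: str,
        universe: list[str],
        refresh: bool = False,
        known_codes: Optional[set[str]] = None,
    ) -> dict[str, bool]:
        """Fetch and cache the KGML of every universe pathway for one organism.

        Returns pathway number -> present flag. A warm cache incurs no
        network traffic unless ``refresh`` is set. Transport failures
        are collected and re-raised at the end as a partial-sync error
        naming the failed numbers, so one flaky request does not lose
        the rest of the run.
        """
        if known_codes is not None and code not in known_codes:
            raise ValueError(f"unknown organism code: {code!r}")
        org_dir = self.cache_dir / code
        org_dir.mkdir(parents=True, exist_ok=True)
        result: dict[str, bool] = {}
        failed: list[str] = []
        for number in [validate_pathway_number(n) for n in universe]:
            xml_path = org_dir / f"{code}{number}.xml"
            absent_path = org_dir / f"{code}{number}.absent"
            if not refresh:
                if xml_path.exists():
                    result[number] = True
                    continue
                if absent_path.exists():
                    result[number] = False
                    continue
            try:
                body = self._get(f"{KEGG_BASE_URL}/get/{code}{number}/kgml")
                if not body.strip():
                    raise _AbsentPathway(number)
                xml_path.write_bytes(body)
                absent_path.unlink(missing_ok=True)
                result[number] = True
            except _AbsentPathway:
                logger.info("pathway %s absent for organism %s", number, code)
                absent_path.write_text("")
                xml_path.unlink(missing_ok=True)
                result[number] = False
            except RetrievalError as exc:
                logger.warning("failed to sync %s%s: %s", code, number, exc)
                failed.append(number)
        if failed:
            raise RetrievalError(
                f"partial sync for {code}: failed pathways {', '.join(failed)}"
            )
        return result

    def organism_cache_dir(self, code: str) -> Path:
        return self.cache_dir / code
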