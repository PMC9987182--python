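"""Link-domain extraction, frequency tables and TLD prevalence ratios.

Domains are full hostnames (lowercased, leading ``www.`` stripped,
subdomains preserved — blog platforms and newspaper sections are distinct
sources).  Hostnames on the shortener/alias exclusion list are rejected:
those URLs point through an indirection service, not at a source.  URL
unshortening is a pluggable resolver (a static alias map by default; no
network access).
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping
from urllib.parse import urlsplit

import pandas as pd

from .affinity_spaces import AffinitySpace
from .errors import UndefinedMetricError, URLRejectedError

__all__ = [
    "DEFAULT_SHORTENERS",
    "static_resolver",
    "extract_domain",
    "domain_table",
    "tld_ratios",
]

#: Hostnames treated as pure aliases/automation, never as content sources.
DEFAULT_SHORTENERS: frozenset[str] = frozenset({"bit.ly"})

Resolver = Callable[[str], str]


def static_resolver(alias_map: Mapping[str, str] | None = None) -> Resolver:
    """A no-network URL resolver backed by a static alias map.

    URLs found in the map are replaced by their expanded form; everything
    else passes through unchanged.
    """
    table = dict(alias_map or {})

    def resolve(url: str) -> str:
        return table.get(url, url)

    return resolve


def extract_domain(
    url: str,
    shorteners: Iterable[str] = DEFAULT_SHORTENERS,
    resolver: Resolver | None = None,
) -> str:
    """Hostname of a URL, lowercased, without a leading ``www.``.

    Raises :class:`URLRejectedError` (with a reason) for URLs that do not
    parse to an http(s) hostname or whose hostname is a listed shortener.
    """
    if resolver is not None:
        url = resolver(url)
    try:
        parts = urlsplit(url.strip())
    except ValueError as exc:
        raise URLRejectedError(url, f"unparseable: {exc}") from exc
    host = (parts.hostname or "").lower()
    if parts.scheme not in ("http", "https") or not host:
        raise URLRejectedError(url, "not an http(s) URL with a hostname")
    if host.startswith("www."):
        host = host[4:]
    if host in {s.lower() for s in shorteners}:
        raise URLRejectedError(url, f"shortener/alias host {host!r}")
    return host


def _accepted_links(
    space: AffinitySpace,
    shorteners: Iterable[str],
    resolver: Resolver | None,
) -> Iterable[tuple[str, str]]:
    """Yield (author_id-qualified tweet, domain) per accepted link occurrence."""
    for t in space.tweets:
        for url in t.urls:
            try:
                yield t, extract_domain(url, shorteners, resolver)
            except URLRejectedError:
                continue


def domain_table(
    space: AffinitySpace,
    top_n: int | None = None,
    shorteners: Iterable[str] = DEFAULT_SHORTENERS,
    resolver: Resolver | None = None,
) -> pd.DataFrame:
    """Ranked (domain, tweets, unique users) table of linked domains.

    A tweet counts once per domain however many links to it it carries;
    ``unique_users_n`` is the number of distinct authors of those tweets.
    Rows are ranked by tweet count descending, ties alphabetical.
    """
    tweet_ids: dict[str, set[str]] = {}
    user_ids: dict[str, set[str]] = {}
    for t, domain in _accepted_links(space, shorteners, resolver):
        tweet_ids.setdefault(domain, set()).add(t.tweet_id)
        user_ids.setdefault(domain, set()).add(t.author_id)
    rows = sorted(
        ((d, len(tweet_ids[d]), len(user_ids[d])) for d in tweet_ids),
        key=lambda r: (-r[1], r[0]),
    )
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(rows, columns=["domain", "tweets_n", "unique_users_n"])


def tld_ratios(
    space: AffinitySpace,
    shorteners: Iterable[str] = DEFAULT_SHORTENERS,
    resolver: Resolver | None = None,
) -> tuple[float, float]:
    """Prevalence of commercial links: (.com/.org, .com/.gov) count ratios.

    Counts accepted link *occurrences* whose hostname ends in ``.com``,
    ``.org`` or ``.gov``; each ratio to 1 decimal.  A zero denominator with
    a nonzero numerator raises :class:`UndefinedMetricError`; with no .com
    links at all both ratios are 0.0.
    """
    counts = {"com": 0, "org": 0, "gov": 0}
    for _, domain in _accepted_links(space, shorteners, resolver):
        for tld in counts:
            if domain == tld or domain.endswith("." + tld):
                counts[tld] += 1
    if counts["com"] == 0:
        return 0.0, 0.0
    ratios = []
    for den in ("org", "gov"):
        if counts[den] == 0:
            raise UndefinedMetricError(f"no .{den} links; ratio undefined")
        ratios.append(round(counts["com"] / counts[den], 1))
    return ratios[0], ratios[1]
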