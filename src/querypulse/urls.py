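"""Clicked-URL classification: registrable domain, TLD class, content, advocacy.

The registrable domain (second-level label plus public suffix, subdomains
stripped, multi-part suffixes like ``co.uk`` and ``state.us`` preserved) is
extracted against a frozen public-suffix snapshot shipped with the package.
Each domain then receives a TLD category from ordered suffix rules, a content
category and an optional advocacy view from an exact-lookup registry, and a
combined class label such as ``"retail content, .com"``.
"""

from __future__ import annotations

import ipaddress
from dataclasses import dataclass, field
from importlib import resources
from urllib.parse import urlsplit

import pandas as pd
import yaml

from .errors import ConfigError, UrlParseError

TLD_COMMERCIAL = "commercial"
TLD_NONCOMMERCIAL = "noncommercial"
TLD_GOVERNMENT = "government"
TLD_EDUCATIONAL = "educational_institution"
TLD_OTHER = "other"

CONTENT_CATEGORIES = ("retail", "news", "educational", "showbiz", "other")
ADVOCACY_VIEWS = ("gun_rights", "gun_control")

#: ordered (suffix, category) rules; first match wins, so the specific
#: ``state.us`` government rule shadows the generic ``us`` country code.
DEFAULT_TLD_RULES: list[tuple[str, str]] = [
    ("state.us", TLD_GOVERNMENT),
    ("gov", TLD_GOVERNMENT),
    ("mil", TLD_GOVERNMENT),
    ("com", TLD_COMMERCIAL),
    ("org", TLD_NONCOMMERCIAL),
    ("edu", TLD_EDUCATIONAL),
]

_TLD_TOKEN = {
    TLD_COMMERCIAL: ".com",
    TLD_NONCOMMERCIAL: ".org",
    TLD_GOVERNMENT: ".gov",
    TLD_EDUCATIONAL: ".edu",
    TLD_OTHER: ".other",
}


def _load_suffixes() -> frozenset[str]:
    text = (
        resources.files("querypulse.data")
        .joinpath("public_suffixes.txt")
        .read_text()
    )
    rules = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            rules.add(line)
    return frozenset(rules)


PUBLIC_SUFFIXES: frozenset[str] = _load_suffixes()


def extract_domain(url: str) -> str:
    """Registrable domain of a URL, lowercased, subdomains stripped.

    ``http://en.wikipedia.org/wiki/X`` → ``wikipedia.org``;
    ``http://portal.ct.state.us/page`` → ``ct.state.us``.

    Raises :class:`UrlParseError` when no registrable domain exists (empty
    host, bare suffix, IP address literal).
    """
    if not url:
        raise UrlParseError("empty URL")
    try:
        parts = urlsplit(url if "//" in url else "//" + url)
        host = parts.hostname
    except ValueError as exc:
        raise UrlParseError(f"unparseable URL {url!r}: {exc}") from exc
    if not host:
        raise UrlParseError(f"no host in URL {url!r}")
    host = host.rstrip(".").lower()
    try:
        ipaddress.ip_address(host)
    except ValueError:
        pass
    else:
        raise UrlParseError(f"IP address host in URL {url!r}")
    if host in PUBLIC_SUFFIXES:
        raise UrlParseError(f"host {host!r} is a bare public suffix")
    labels = host.split(".")
    if len(labels) < 2 or not all(labels):
        raise UrlParseError(f"host {host!r} has no registrable domain")

    # longest matching known suffix; unknown TLDs fall back to the final label
    suffix_len = 1
    for take in range(len(labels) - 1, 0, -1):
        if ".".join(labels[-take:]) in PUBLIC_SUFFIXES:
            suffix_len = take
            break
    if suffix_len >= len(labels):
        raise UrlParseError(f"host {host!r} is a bare public suffix")
    return ".".join(labels[-(suffix_len + 1):])


@dataclass
class DomainRegistry:
    """Domain → content category and advocacy view lookups, plus TLD rules."""

    content_map: dict[str, str]
    advocacy_map: dict[str, str] = field(default_factory=dict)
    tld_rules: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_TLD_RULES))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for domain, cat in self.content_map.items():
            if domain != domain.lower() or "/" in domain or ":" in domain:
                raise ConfigError(f"registry: domain {domain!r} must be bare lowercase")
            if cat not in CONTENT_CATEGORIES:
                raise ConfigError(f"registry: unknown content category {cat!r}")
        for domain, view in self.advocacy_map.items():
            if view not in ADVOCACY_VIEWS:
                raise ConfigError(f"registry: unknown advocacy view {view!r}")
        for _, cat in self.tld_rules:
            if cat not in (TLD_COMMERCIAL, TLD_NONCOMMERCIAL, TLD_GOVERNMENT,
                           TLD_EDUCATIONAL, TLD_OTHER):
                raise ConfigError(f"registry: unknown TLD category {cat!r}")

    @classmethod
    def from_yaml(cls, path) -> "DomainRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        content: dict[str, str] = {}
        for cat, domains in data.get("content", {}).items():
            for domain in domains:
                if domain in content:
                    raise ConfigError(
                        f"registry: domain {domain!r} listed under both "
                        f"'{content[domain]}' and '{cat}'"
                    )
                content[domain] = cat
        advocacy: dict[str, str] = {}
        for view, domains in data.get("advocacy", {}).items():
            for domain in domains:
                if domain in advocacy:
                    raise ConfigError(
                        f"registry: domain {domain!r} has two advocacy views"
                    )
                advocacy[domain] = view
        return cls(content_map=content, advocacy_map=advocacy)

    def domains(self) -> set[str]:
        return set(self.content_map) | set(self.advocacy_map)


def tld_category(domain: str, rules: list[tuple[str, str]] | None = None) -> str:
    """First matching ordered suffix rule; fallback ``other``."""
    rules = DEFAULT_TLD_RULES if rules is None else rules
    for suffix, category in rules:
        if domain == suffix or domain.endswith("." + suffix):
            return category
    return TLD_OTHER


def content_category(domain: str, registry: DomainRegistry) -> str:
    """Exact registry lookup; unlisted domains are ``other``."""
    return registry.content_map.get(domain, "other")


def advocacy_view(domain: str, registry: DomainRegistry) -> str | None:
    return registry.advocacy_map.get(domain)


def class_label(content: str, tld: str) -> str:
    """Combined class, e.g. ``("retail", "commercial")`` → ``"retail content, .com"``."""
    return f"{content} content, {_TLD_TOKEN[tld]}"


@dataclass(frozen=True)
class UrlClassification:
    domain: str
    tld_category: str
    content_category: str
    advocacy: str | None
    class_label: str


def classify_url(url: str, registry: DomainRegistry) -> UrlClassification:
    """Pure per-URL classification; raises :class:`UrlParseError` on bad URLs."""
    domain = extract_domain(url)
    tld = tld_category(domain, registry.tld_rules)
    content = content_category(domain, registry)
    return UrlClassification(
        domain=domain,
        tld_category=tld,
        content_category=content,
        advocacy=advocacy_view(domain, registry),
        class_label=class_label(content, tld),
    )


def classify_urls(urls: pd.Series, registry: DomainRegistry) -> tuple[pd.DataFrame, int]:
    """Vectorised URL classification over a log column.

    Unparseable URLs are kept (totals stay conserved) with an empty domain
    and the ``other`` classes; the second return value tallies them.
    """
    fallback = UrlClassification(
        domain="",
        tld_category=TLD_OTHER,
        content_category="other",
        advocacy=None,
        class_label=class_label("other", TLD_OTHER),
    )
    mapping: dict[str, UrlClassification] = {}
    errors_by_url: dict[str, bool] = {}
    for url in pd.unique(urls):
        try:
            mapping[url] = classify_url(url, registry)
            errors_by_url[url] = False
        except UrlParseError:
            mapping[url] = fallback
            errors_by_url[url] = True
    frame = pd.DataFrame(
        {
            "domain": urls.map(lambda u: mapping[u].domain),
            "tld_category": urls.map(lambda u: mapping[u].tld_category),
            "content_category": urls.map(lambda u: mapping[u].content_category),
            "advocacy": urls.map(lambda u: mapping[u].advocacy),
            "class_label": urls.map(lambda u: mapping[u].class_label),
        },
        index=urls.index,
    )
    n_errors = int(urls.map(errors_by_url).sum())
    return frame, n_errors
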