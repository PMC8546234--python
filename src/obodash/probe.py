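"""Live homepage probing (stdlib urllib, HEAD with GET fallback).

The checks depend only on the URL -> HTTP status contract, so tests and
offline runs substitute a stub; this module supplies the one real
implementation for online dashboard runs.
"""

from __future__ import annotations

import urllib.error
import urllib.request

__all__ = ["http_probe"]

_MAX_REDIRECTS = 5
_TIMEOUT_SECONDS = 10.0


def http_probe(url: str, timeout: float = _TIMEOUT_SECONDS) -> int:
    """Return the final HTTP status for ``url`` (following up to 5
    redirects), trying HEAD first and falling back to GET."""
    opener = urllib.request.build_opener(
        urllib.request.HTTPRedirectHandler()
    )
    opener.handlers[0].max_redirections = _MAX_REDIRECTS  # type: ignore[attr-defined]
    for method in ("HEAD", "GET"):
        request = urllib.request.Request(url, method=method)
        try:
            with opener.open(request, timeout=timeout) as response:
                return response.status
        except urllib.error.HTTPError as exc:
            if method == "GET" or exc.code not in (405, 501):
                return exc.code
        # transport errors propagate: the caller treats them as non-resolution
    raise RuntimeError("unreachable")
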