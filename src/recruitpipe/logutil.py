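"""Line-delimited JSON logging for pipeline runs."""

from __future__ import annotations

import json
import logging
import sys
import time

__all__ = ["setup_logging", "get_logger"]


class _JsonFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        entry = {
            "ts": round(time.time(), 3),
            "level": record.levelname.lower(),
            "logger": record.name,
            "msg": record.getMessage(),
        }
        extra = getattr(record, "params", None)
        if extra:
            entry["params"] = extra
        return json.dumps(entry, sort_keys=True, default=str)


def setup_logging(level: int = logging.INFO, stream=None) -> None:
    handler = logging.StreamHandler(stream or sys.stderr)
    handler.setFormatter(_JsonFormatter())
    root = logging.getLogger("recruitpipe")
    root.handlers[:] = [handler]
    root.setLevel(level)


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"recruitpipe.{name}")
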