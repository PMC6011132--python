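"""Run configuration: a flat key=value text file that round-trips losslessly."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .primer_screening import PrimerConstraints
from .ssr_mining import MiningThresholds


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond its input files."""

    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    primer_constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    n_permutations: int = 10_000
    seed: int = 0
    adjust_method: str = "bonferroni"
    out_dir: str = "ssrkit_out"
    log_level: str = "INFO"
    top_k_primers: int = 3

    def to_text(self) -> str:
        pc = self.primer_constraints
        items = {
            "min_repeats": ",".join(
                str(self.thresholds[k]) for k in range(1, 7)
            ),
            "product_min": pc.product_min,
            "product_max": pc.product_max,
            "primer_min": pc.primer_min,
            "primer_max": pc.primer_max,
            "primer_opt": pc.primer_opt,
            "gc_min": pc.gc_min,
            "gc_max": pc.gc_max,
            "tm_min": pc.tm_min,
            "tm_max": pc.tm_max,
            "max_tm_diff": pc.max_tm_diff,
            "w_tm": pc.w_tm,
            "w_gc": pc.w_gc,
            "max_complementarity_run": pc.max_complementarity_run,
            "salt_na_mM": pc.salt_na_mM,
            "oligo_nM": pc.oligo_nM,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "adjust_method": self.adjust_method,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "top_k_primers": self.top_k_primers,
        }
        return "\n".join(f"{k}={v}" for k, v in items.items()) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kv: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()

        def geti(key: str, default: int) -> int:
            return int(kv.get(key, default))

        def getf(key: str, default: float) -> float:
            return float(kv.get(key, default))

        thresholds = (
            MiningThresholds.from_csv(kv["min_repeats"])
            if "min_repeats" in kv
            else MiningThresholds()
        )
        dpc = PrimerConstraints()
        pc = PrimerConstraints(
            product_min=geti("product_min", dpc.product_min),
            product_max=geti("product_max", dpc.product_max),
            primer_min=geti("primer_min", dpc.primer_min),
            primer_max=geti("primer_max", dpc.primer_max),
            primer_opt=geti("primer_opt", dpc.primer_opt),
            gc_min=getf("gc_min", dpc.gc_min),
            gc_max=getf("gc_max", dpc.gc_max),
            tm_min=getf("tm_min", dpc.tm_min),
            tm_max=getf("tm_max", dpc.tm_max),
            max_tm_diff=getf("max_tm_diff", dpc.max_tm_diff),
            w_tm=getf("w_tm", dpc.w_tm),
            w_gc=getf("w_gc", dpc.w_gc),
            max_complementarity_run=geti(
                "max_complementarity_run", dpc.max_complementarity_run
            ),
            salt_na_mM=getf("salt_na_mM", dpc.salt_na_mM),
            oligo_nM=getf("oligo_nM", dpc.oligo_nM),
        )
        return cls(
            thresholds=thresholds,
            primer_constraints=pc,
            n_permutations=geti("n_permutations", 10_000),
            seed=geti("seed", 0),
            adjust_method=kv.get("adjust_method", "bonferroni"),
            out_dir=kv.get("out_dir", "ssrkit_out"),
            log_level=kv.get("log_level", "INFO"),
            top_k_primers=geti("top_k_primers", 3),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @property
    def config_hash(self) -> str:
        """Hash of the computational parameters only (where results go and
        how chatty the log is cannot change the numbers)."""
        lines = [
            ln for ln in self.to_text().splitlines()
            if not ln.startswith(("out_dir=", "log_level="))
        ]
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:12]

    def provenance_header(self) -> str:
        """Comment line stamped at the top of every output file."""
        return f"# ssrkit config={self.config_hash} seed={self.seed}\n"
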