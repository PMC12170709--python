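"""Optional adapter for estimating chemical potentials with external tools.

The estimation workflow mirrors the standard semi-empirical route: write
the molecular graph as an SDF, generate and force-field-optimize a 3D
embedding (Open Babel), then run a semi-empirical geometry optimization and
thermochemistry calculation (xTB) at the configured temperature/pressure to
obtain G°.  The pipeline's correctness never depends on this module: the
rest of the package runs from the shipped DrG fixture, and tests exercise
this contract with a mocked toolchain.

Backends are invoked through subprocesses behind a narrow interface so the
whole stage can be replaced by a stub.  A missing executable yields a
:class:`NotAvailable` outcome (distinct from a genuine failure).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .molecules import Molecule
from .thermo import PotentialTable, STANDARD_P, STANDARD_T


class QMError(RuntimeError):
    """An external stage ran but failed (e.g. non-converged optimization)."""


@dataclass
class NotAvailable:
    """A required backend executable is not installed."""

    missing: str

    def __bool__(self) -> bool:  # truthiness signals "usable result"
        return False


def molecule_to_sdf(m: Molecule, title: str = "") -> str:
    """Minimal V2000 SDF of the heavy-atom graph (no coordinates)."""
    nodes = sorted(m.graph.nodes)
    pos = {v: i + 1 for i, v in enumerate(nodes)}
    lines = [title or (m.name or "molecule"), "  nogmap", ""]
    lines.append(f"{len(nodes):3d}{m.graph.number_of_edges():3d}"
                 "  0  0  0  0  0  0  0  0999 V2000")
    for v in nodes:
        el = m.graph.nodes[v]["element"]
        lines.append(f"    0.0000    0.0000    0.0000 {el:<3} 0  0  0  0  0"
                     "  0  0  0  0  0  0  0")
    for u, v, d in m.graph.edges(data=True):
        lines.append(f"{pos[u]:3d}{pos[v]:3d}{d['order']:3d}  0  0  0  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


@dataclass
class ExternalToolchain:
    """Paths and settings for the embedding/optimization backends."""

    obabel: str = "obabel"
    xtb: str = "xtb"
    temperature: float = STANDARD_T
    pressure: float = STANDARD_P
    workdir: Optional[Path] = None

    def probe(self) -> Optional[NotAvailable]:
        for exe in (self.obabel, self.xtb):
            if shutil.which(exe) is None:
                return NotAvailable(missing=exe)
        return None

    # -- stage implementations (subprocess; mocked in tests) ---------------
    def embed(self, sdf_in: Path, sdf_out: Path) -> None:
        res = subprocess.run(
            [self.obabel, str(sdf_in), "-O", str(sdf_out), "--gen3d", "--ff",
             "UFF"],
            capture_output=True, text=True,
        )
        if res.returncode != 0 or not sdf_out.exists():
            raise QMError(f"3D embedding failed: {res.stderr.strip()}")

    def thermochemistry(self, sdf_in: Path) -> float:
        """Optimize geometry and return G° in kJ/mol."""
        res = subprocess.run(
            [self.xtb, str(sdf_in), "--opt", "--thermo",
             f"--etemp", str(self.temperature)],
            capture_output=True, text=True, cwd=str(sdf_in.parent),
        )
        if res.returncode != 0:
            raise QMError(f"xtb failed: {res.stderr.strip()[:500]}")
        for line in reversed(res.stdout.splitlines()):
            if "TOTAL FREE ENERGY" in line.upper():
                hartree = float(line.split()[-3])
                return hartree * 2625.4996  # Eh -> kJ/mol
        raise QMError("xtb output contained no free energy")


@dataclass
class QMJob:
    """Stage record for one molecule."""

    molecule: Molecule
    embedded_sdf: Optional[Path] = None
    optimized_sdf: Optional[Path] = None
    g_standard: Optional[float] = None
    status: Dict[str, str] = field(default_factory=dict)


def estimate_potential(m: Molecule, backend: ExternalToolchain,
                       workdir: Optional[Path] = None):
    """G° of one molecule via the external toolchain.

    Returns a float (kJ/mol) on success, or :class:`NotAvailable` when a
    backend executable is missing; raises :class:`QMError` on stage failure.
    """
    missing = backend.probe()
    if missing is not None:
        return missing
    import tempfile

    job = QMJob(molecule=m)
    with tempfile.TemporaryDirectory() as td:
        base = Path(workdir or td)
        raw = base / "input.sdf"
        raw.write_text(molecule_to_sdf(m))
        emb = base / "embedded.sdf"
        backend.embed(raw, emb)
        job.embedded_sdf = emb
        job.status["embed"] = "ok"
        g = backend.thermochemistry(emb)
        job.status["thermo"] = "ok"
        job.g_standard = g
    return job.g_standard


def build_potential_table(molecules: Dict[str, Molecule],
                          backend: ExternalToolchain) -> PotentialTable:
    """Per-molecule potentials for a whole network; all-or-nothing."""
    pots = {}
    for key, m in molecules.items():
        g = estimate_potential(m, backend)
        if isinstance(g, NotAvailable):
            raise QMError(f"backend missing: {g.missing}")
        pots[key] = g
    return PotentialTable(pots, temperature=backend.temperature,
                          pressure=backend.pressure, source="qm-adapter")
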