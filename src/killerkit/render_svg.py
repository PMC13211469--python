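"""Minimal SVG renderers for annotation reports.

Two figures are produced: a linear domain diagram of a preprotoxin
(domains to scale, cleavage-site ticks, cysteine lollipops, disulfide arcs,
hatched membrane-interacting spans) and a helical wheel with the five-class
residue coloring (hydrophobic black, positive yellow, negative blue, polar
purple, aromatic orange). Output is plain SVG text.
"""

from __future__ import annotations

import math
from xml.sax.saxutils import escape

from .maturation import DomainPartition
from .struct_metrics import HelixGeometry

DOMAIN_COLORS = {
    "delta": "#444444",
    "alpha": "#e6b800",
    "gamma": "#4dbbd5",
    "beta": "#3c5488",
}

WHEEL_COLORS = {
    "hydrophobic": "#000000",
    "positive": "#e6b800",
    "negative": "#3c5488",
    "polar": "#7e6148",
    "aromatic": "#ff7f0e",
}
WHEEL_TEXT = {
    "hydrophobic": "#ffffff", "positive": "#000000", "negative": "#ffffff",
    "polar": "#ffffff", "aromatic": "#000000",
}


def domain_diagram_svg(
    sequence_length: int,
    partition: DomainPartition,
    cleavage_sites: list[int] | None = None,
    cysteines: list[int] | None = None,
    disulfide_pairs: list[tuple[int, int]] | None = None,
    hatched_spans: list[tuple[int, int]] | None = None,
    title: str = "",
    width: int = 720,
) -> str:
    """Linear to-scale domain diagram of one preprotoxin."""
    margin, bar_y, bar_h = 40, 90, 26
    scale = (width - 2 * margin) / sequence_length
    height = 160

    def x(pos: float) -> float:
        return margin + pos * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="11">',
        '<defs><pattern id="hatch" width="6" height="6" patternUnits="userSpaceOnUse" '
        'patternTransform="rotate(45)"><line x1="0" y1="0" x2="0" y2="6" '
        'stroke="#ffffff" stroke-width="2"/></pattern></defs>',
    ]
    if title:
        parts.append(f'<text x="{margin}" y="20" font-size="14">{escape(title)}</text>')
    # backbone line for regions outside named domains (e.g. the signal region)
    parts.append(
        f'<line x1="{x(0):.1f}" y1="{bar_y + bar_h / 2}" x2="{x(sequence_length):.1f}" '
        f'y2="{bar_y + bar_h / 2}" stroke="#999" stroke-width="2"/>'
    )
    for seg in partition:
        color = DOMAIN_COLORS.get(seg.name, "#888888")
        x0, x1 = x(seg.start - 1), x(seg.end)
        parts.append(
            f'<rect x="{x0:.1f}" y="{bar_y}" width="{x1 - x0:.1f}" height="{bar_h}" '
            f'fill="{color}" stroke="#222"/>'
        )
        parts.append(
            f'<text x="{(x0 + x1) / 2:.1f}" y="{bar_y + bar_h + 14}" '
            f'text-anchor="middle">{escape(seg.name)} {seg.start}-{seg.end}</text>'
        )
    for start, end in hatched_spans or []:
        x0, x1 = x(start - 1), x(end)
        parts.append(
            f'<rect x="{x0:.1f}" y="{bar_y}" width="{x1 - x0:.1f}" height="{bar_h}" '
            f'fill="url(#hatch)" stroke="none"/>'
        )
    for pos in cleavage_sites or []:
        parts.append(
            f'<line x1="{x(pos):.1f}" y1="{bar_y - 8}" x2="{x(pos):.1f}" '
            f'y2="{bar_y + bar_h + 4}" stroke="#cc0000" stroke-width="1.5"/>'
        )
        parts.append(
            f'<text x="{x(pos):.1f}" y="{bar_y - 12}" text-anchor="middle" '
            f'font-size="9" fill="#cc0000">{pos}</text>'
        )
    for pos in cysteines or []:
        parts.append(
            f'<line x1="{x(pos):.1f}" y1="{bar_y}" x2="{x(pos):.1f}" '
            f'y2="{bar_y - 18}" stroke="#222"/>'
            f'<circle cx="{x(pos):.1f}" cy="{bar_y - 22}" r="3.5" fill="#f3a712" '
            f'stroke="#222"/>'
        )
    for a, b in disulfide_pairs or []:
        xa, xb = x(a), x(b)
        mid = (xa + xb) / 2
        ry = min(30.0, abs(xb - xa) / 3 + 8)
        parts.append(
            f'<path d="M {xa:.1f} {bar_y - 26} Q {mid:.1f} {bar_y - 26 - ry:.1f} '
            f'{xb:.1f} {bar_y - 26}" fill="none" stroke="#222" stroke-dasharray="3,2"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def helical_wheel_svg(geometry: HelixGeometry, title: str = "", size: int = 360) -> str:
    """Helical wheel of a residue window; stroke width thins N- to C-terminus."""
    cx = cy = size / 2
    radius = size / 2 - 45
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size + 20}" '
        f'font-family="sans-serif" font-size="12">'
    ]
    if title:
        parts.append(f'<text x="{cx}" y="18" text-anchor="middle">{escape(title)}</text>')
    pts = []
    for angle in geometry.wheel_angles:
        rad = math.radians(angle - 90)  # first residue at the top
        pts.append((cx + radius * math.cos(rad), cy + 20 + radius * math.sin(rad)))
    n = len(pts)
    for i in range(n - 1):
        w = 3.0 - 2.4 * i / max(n - 2, 1)
        parts.append(
            f'<line x1="{pts[i][0]:.1f}" y1="{pts[i][1]:.1f}" x2="{pts[i + 1][0]:.1f}" '
            f'y2="{pts[i + 1][1]:.1f}" stroke="#777" stroke-width="{w:.2f}"/>'
        )
    for i, ((px, py), letter, cls) in enumerate(
        zip(pts, geometry.sequence, geometry.residue_classes)
    ):
        fill = WHEEL_COLORS[cls]
        parts.append(
            f'<circle cx="{px:.1f}" cy="{py:.1f}" r="13" fill="{fill}" stroke="#222"/>'
            f'<text x="{px:.1f}" y="{py + 4:.1f}" text-anchor="middle" '
            f'fill="{WHEEL_TEXT[cls]}">{letter}{i + 1}</text>'
        )
    parts.append(
        f'<text x="{cx}" y="{size + 12}" text-anchor="middle" font-size="11">'
        f"&#956;H = {geometry.hydrophobic_moment:.2f}, "
        f"&#9001;H&#9002; = {geometry.mean_hydrophobicity:.2f}</text>"
    )
    parts.append("</svg>")
    return "\n".join(parts)
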