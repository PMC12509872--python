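"""Self-contained interactive HTML output for FigureSpec objects.

The figure data are embedded as JSON and drawn client-side into an SVG:
per-sample polylines (null y-values break the line), hover tooltips showing
the sample's metadata, a clickable legend that toggles groups, and
drag-to-zoom with double-click reset. No external assets are referenced.
"""

from __future__ import annotations

import html
import json
from dataclasses import asdict

_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>__TITLE__</title>
<style>
body { font-family: sans-serif; margin: 1em; }
#tooltip { position: absolute; display: none; background: #fffff0;
  border: 1px solid #888; padding: 4px 6px; font-size: 12px; pointer-events: none; }
#legend span { cursor: pointer; margin-right: 1em; user-select: none; }
#legend .off { opacity: 0.3; text-decoration: line-through; }
svg { border: 1px solid #ddd; }
polyline { fill: none; stroke-width: 1; }
polyline:hover { stroke-width: 2.5; }
</style></head>
<body>
<h3>__TITLE__</h3>
<div id="legend"></div>
<svg id="plot" width="__W__" height="__H__"></svg>
<div id="tooltip"></div>
<script>
var FIG = __FIG_JSON__;
(function () {
  var svg = document.getElementById("plot"), tip = document.getElementById("tooltip");
  var W = FIG.width, H = FIG.height, M = {l: 60, r: 15, t: 25, b: 35};
  var xs = [], ys = [];
  FIG.traces.forEach(function (t) {
    t.x.forEach(function (v) { xs.push(v); });
    t.y.forEach(function (v) { if (v !== null) ys.push(v); });
  });
  var view = {x0: Math.min.apply(null, xs), x1: Math.max.apply(null, xs),
              y0: Math.min.apply(null, ys), y1: Math.max.apply(null, ys)};
  var home = Object.assign({}, view);
  function sx(v) { return M.l + (v - view.x0) / (view.x1 - view.x0 || 1) * (W - M.l - M.r); }
  function sy(v) { return H - M.b - (v - view.y0) / (view.y1 - view.y0 || 1) * (H - M.t - M.b); }
  var hidden = {};
  function draw() {
    svg.innerHTML = "";
    FIG.panels.forEach(function (p, i) {
      if (i > 0) {
        var l = document.createElementNS(svg.namespaceURI, "line");
        l.setAttribute("x1", sx(p.x_start)); l.setAttribute("x2", sx(p.x_start));
        l.setAttribute("y1", M.t); l.setAttribute("y2", H - M.b);
        l.setAttribute("stroke", "#bbb"); l.setAttribute("stroke-dasharray", "4 3");
        svg.appendChild(l);
      }
      var t = document.createElementNS(svg.namespaceURI, "text");
      t.setAttribute("x", (sx(p.x_start) + sx(p.x_end)) / 2);
      t.setAttribute("y", M.t - 8); t.setAttribute("text-anchor", "middle");
      t.setAttribute("font-size", "11"); t.textContent = p.label;
      svg.appendChild(t);
    });
    FIG.traces.forEach(function (tr, ti) {
      if (tr.group !== null && hidden[tr.group]) return;
      var seg = [];
      function flush() {
        if (seg.length > 1) {
          var pl = document.createElementNS(svg.namespaceURI, "polyline");
          pl.setAttribute("points", seg.join(" "));
          pl.setAttribute("stroke", tr.color);
          pl.setAttribute("data-trace", ti);
          svg.appendChild(pl);
        }
        seg = [];
      }
      for (var i = 0; i < tr.x.length; i++) {
        if (tr.y[i] === null) { flush(); continue; }
        seg.push(sx(tr.x[i]) + "," + sy(tr.y[i]));
      }
      flush();
    });
  }
  svg.addEventListener("mousemove", function (ev) {
    var el = ev.target;
    if (el.tagName === "polyline") {
      var tr = FIG.traces[+el.getAttribute("data-trace")];
      tip.innerHTML = tr.hover;
      tip.style.left = (ev.pageX + 12) + "px";
      tip.style.top = (ev.pageY + 12) + "px";
      tip.style.display = "block";
    } else { tip.style.display = "none"; }
  });
  svg.addEventListener("mouseleave", function () { tip.style.display = "none"; });
  var drag = null;
  svg.addEventListener("mousedown", function (ev) { drag = ev.offsetX; });
  svg.addEventListener("mouseup", function (ev) {
    if (drag !== null && Math.abs(ev.offsetX - drag) > 10) {
      var inv = function (px) {
        return view.x0 + (px - M.l) / (W - M.l - M.r) * (view.x1 - view.x0);
      };
      var a = inv(Math.min(drag, ev.offsetX)), b = inv(Math.max(drag, ev.offsetX));
      view.x0 = a; view.x1 = b; draw();
    }
    drag = null;
  });
  svg.addEventListener("dblclick", function () {
    view = Object.assign({}, home); draw();
  });
  var leg = document.getElementById("legend"), groups = [];
  FIG.traces.forEach(function (t) {
    if (t.group !== null && groups.indexOf(t.group) < 0) groups.push(t.group);
  });
  groups.forEach(function (g) {
    var color = "#555";
    FIG.traces.some(function (t) { if (t.group === g) { color = t.color; return true; } });
    var s = document.createElement("span");
    s.innerHTML = "&#9632; " + g;
    s.style.color = color;
    s.onclick = function () {
      hidden[g] = !hidden[g];
      s.className = hidden[g] ? "off" : "";
      draw();
    };
    leg.appendChild(s);
  });
  draw();
})();
</script></body></html>
"""


def render_html(fig, path: str) -> None:
    payload = json.dumps(asdict(fig))
    doc = (_TEMPLATE
           .replace("__TITLE__", html.escape(fig.title))
           .replace("__W__", str(fig.width))
           .replace("__H__", str(fig.height))
           .replace("__FIG_JSON__", payload))
    with open(path, "wt") as fh:
        fh.write(doc)
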