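"""Turner 2004 RNA nearest-neighbor free-energy tables.

All energies are integers in units of 0.01 kcal/mol at 37 degrees C
(negative = stabilizing).  100000 marks undefined entries.

Table layouts (flattened row-major, decoded in :mod:`duplexscan.params`):

* ``STACK``     -- (6, 6); both axes indexed by pair type
  CG, GC, GU, UG, AU, UA.  ``STACK[p1][p2]`` is the stack of pair ``p2``
  on closing pair ``p1``, the second pair read from the opposite strand.
* ``BULGE``, ``INTERNAL`` -- (31,); loop initiation by total unpaired
  length 0..30.
* ``INT11``     -- (6, 6, 5, 5): 1x1 interior loops,
  ``[p1][p2][x][y]`` with nucleotides coded 0=E(none), 1=A, 2=C, 3=G, 4=U.
* ``INT21``     -- (6, 6, 5, 5, 5): 1x2 interior loops.
* ``INT22``     -- (6, 6, 4, 4, 4, 4): 2x2 interior loops, nucleotide
  axes coded 0=A..3=U.
* ``MISMATCH_I``, ``MISMATCH_1N``, ``MISMATCH_23`` -- (6, 5, 5): interior
  terminal-mismatch terms for generic, 1xn (n>2) and 2x3 loops.
* ``NINIO_M`` / ``NINIO_MAX`` -- per-nucleotide interior-loop asymmetry
  slope and its cap.
* ``TERM_AU`` -- helix-end penalty for A-U / G-U closing pairs.
* ``DUPLEX_INIT`` -- intermolecular duplex initiation.
* ``LXC`` -- coefficient of the Jacobson-Stockmayer logarithmic
  extrapolation for loops longer than 30 nt.
"""

INF = 100000

NINIO_M = 60
NINIO_MAX = 300
TERM_AU = 50
DUPLEX_INIT = 410
LXC = 107.856

BULGE = "100000 380 280 320 360 400 440 460 470 480 490 500 510 520 530 540 540 550 550 560 570 570 580 580 580 590 590 600 600 600 610"

INTERNAL = "100000 100000 100 100 110 200 200 210 230 240 250 260 270 280 290 290 300 310 310 320 330 330 340 340 350 350 350 360 360 370 370"

STACK = "-240 -330 -210 -140 -210 -210 -330 -340 -250 -150 -220 -240 -210 -250 130 -50 -140 -130 -140 -150 -50 30 -60 -100 -210 -220 -140 -60 -110 -90 -210 -240 -130 -100 -90 -130"

MISMATCH_I = "0 0 0 0 0 0 0 0 -80 0 0 0 0 0 0 0 -100 0 -100 0 0 0 0 0 -60 0 0 0 0 0 0 0 0 -80 0 0 0 0 0 0 0 -100 0 -100 0 0 0 0 0 -60 70 70 70 70 70 70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30 70 70 70 70 70 10 70 70 70 70 70 70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30 70 70 70 70 70 10 70 70 70 70 70 70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30 70 70 70 70 70 10 70 70 70 70 70 70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30 70 70 70 70 70 10"

MISMATCH_1N = "0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70"

MISMATCH_23 = "0 0 0 0 0 0 0 0 -50 0 0 0 0 0 0 0 -110 0 -70 0 0 0 0 0 -30 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 -120 0 -70 0 0 0 0 0 -30 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 -40 70 0 70 70 70 70 70 40 70 70 70 70 70 70 70 70 20 70 70 70 70 70 70 70 -40 70 0 70 70 70 70 70 40 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 70 -40 70 0 70 70 70 70 70 40 70 70 70 70 70 70 70 70 20 70 70 70 70 70 70 70 -40 70 0 70 70 70 70 70 40"

INT11 = "90 90 50 50 50 90 90 50 50 50 50 50 50 50 50 50 50 50 -140 50 50 50 50 50 40 90 90 50 50 60 90 90 -40 50 50 60 30 50 50 60 50 -10 50 -220 50 50 50 0 50 -10 120 120 120 120 120 120 60 50 120 120 120 120 120 120 120 120 -20 120 -140 120 120 120 100 120 110 220 220 170 120 120 220 220 130 120 120 170 120 170 120 120 120 120 120 -140 120 120 120 120 120 110 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 80 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 120 90 90 60 50 50 90 90 30 -10 50 50 -40 50 50 0 50 50 50 -220 50 60 50 60 50 -10 80 80 50 50 50 80 80 50 50 50 50 50 50 50 50 50 50 50 -230 50 50 50 50 50 -60 190 190 120 150 150 190 190 120 150 120 120 120 120 120 120 120 120 120 -140 120 150 120 120 120 150 160 160 120 120 120 160 160 120 100 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 70 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 80 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 120 120 120 120 120 120 120 60 120 -20 120 120 50 120 120 100 120 120 120 -140 120 120 120 120 120 110 190 190 120 120 150 190 190 120 120 120 120 120 120 120 120 150 150 120 -140 120 150 120 120 120 150 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 220 220 170 120 120 220 220 120 120 120 170 130 170 120 120 120 120 120 -140 120 120 120 120 120 110 160 160 120 120 120 160 160 120 120 120 120 120 120 120 120 120 100 120 -140 120 120 120 120 120 70 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 190 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 80 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 80 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 150 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120 120 120 120 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 150 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 170"

INT21 = "230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 110 230 230 230 230 110 230 230 230 230 110 230 110 110 110 110 110 230 230 230 110 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 110 230 110 230 110 110 110 110 110 230 110 230 110 230 110 110 110 110 110 230 110 230 110 230 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 150 150 150 150 150 250 250 250 230 230 250 250 230 230 230 250 230 250 230 230 230 230 230 230 230 250 250 230 230 230 250 250 230 110 230 250 250 230 110 230 230 230 170 110 230 110 80 110 110 110 230 230 230 110 230 250 250 250 230 230 230 230 230 230 230 250 230 250 230 230 230 230 230 230 230 250 250 230 230 230 230 170 230 110 230 230 170 230 80 230 230 110 230 110 230 120 120 110 110 110 230 110 230 110 230 230 230 230 230 150 230 230 230 230 150 230 230 220 230 150 230 230 230 230 150 170 150 170 150 140 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 250 250 230 230 230 250 250 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 250 250 230 230 230 250 250 230 210 230 230 230 230 230 230 120 120 110 110 110 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 190 230 230 230 110 230 110 230 110 110 110 110 110 230 110 230 110 230 110 110 110 110 110 230 110 230 110 230 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 150 150 150 150 150 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 110 110 110 110 110 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 230 110 230 110 230 230 110 230 110 230 230 110 230 110 230 110 110 110 110 110 230 110 230 110 230 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 230 230 230 230 150 150 150 150 150 150 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 250 300 210 300 300 300 300 300 300 190 120 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 250 300 210 300 300 300 300 300 300 190 120 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 250 370 210 370 370 370 370 370 370 260 120 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 190 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 190 190 190 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 260 260 260 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 300 300 300 190 300 300 300 300 190 300 190 190 190 190 190 300 300 300 190 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 300 190 300 190 300 300 190 300 190 300 300 190 300 190 300 190 190 190 190 190 300 190 300 190 300 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 300 300 300 300 220 220 220 220 220 220 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 370 260 370 260 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 370 370 370 260 370 370 370 370 260 370 260 260 260 260 260 370 370 370 260 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 260 260 260 260 260 370 260 370 260 370 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 370 370 370 370 300 300 300 300 300 300"

INT22 = "120 160 20 160 110 150 20 150 20 60 -70 60 110 150 20 150 160 200 60 200 140 180 110 180 160 200 60 200 130 170 90 170 20 60 -70 60 110 150 20 150 -30 10 0 10 110 150 20 150 160 200 60 200 130 170 90 170 160 200 60 200 100 80 -50 80 110 140 110 130 110 140 110 120 20 110 20 90 110 140 110 120 150 180 150 170 140 170 140 150 150 180 150 170 120 150 120 140 20 110 20 90 110 140 110 120 -40 -10 -40 -20 110 140 110 120 150 180 150 170 120 150 120 140 150 180 150 170 30 60 30 50 20 160 -30 160 20 150 -40 150 -70 60 0 60 20 150 -40 150 60 200 10 200 110 180 -10 180 60 200 10 200 90 170 -20 170 -70 60 0 60 20 150 -40 150 0 10 80 10 20 150 -40 150 60 200 10 200 90 170 -20 170 60 200 10 200 -50 80 20 80 110 130 110 100 110 120 110 30 20 90 20 -50 110 120 110 30 150 170 150 80 140 150 140 60 150 170 150 80 120 140 120 50 20 90 20 -50 110 120 110 30 -40 -20 -40 20 110 120 110 30 150 170 150 80 120 140 120 50 150 170 150 80 30 50 30 -40 130 60 0 170 110 150 -70 150 -30 10 -160 -30 110 150 10 150 100 50 -100 140 110 150 -60 150 100 140 10 140 110 150 70 150 40 30 -70 30 110 150 10 150 -30 -30 0 10 110 150 10 150 100 140 10 140 110 150 80 150 100 140 10 140 150 0 90 70 130 220 130 140 100 130 100 120 -70 70 -70 0 100 130 100 120 110 190 100 110 100 130 100 120 100 130 100 110 100 130 100 170 70 70 -10 60 100 130 100 120 -40 -10 -40 20 100 130 100 120 100 130 100 110 110 140 110 120 100 130 100 110 -20 -10 30 20 -20 170 -10 170 -40 150 -40 150 -170 -30 -90 -30 10 150 -40 150 70 140 -50 140 70 150 -40 150 10 140 -50 140 70 150 20 150 -50 30 -30 30 10 150 -40 150 -30 10 80 10 10 150 -40 150 10 140 -50 140 80 150 -50 150 10 140 -50 140 90 70 140 70 130 140 130 140 100 120 100 30 -70 0 -70 50 100 120 100 30 100 110 100 30 100 120 100 30 100 110 100 20 100 120 100 30 -10 50 -10 140 100 120 100 30 -40 -60 -40 70 100 120 100 30 100 110 100 20 110 120 110 30 100 110 100 20 30 40 30 -60 270 300 170 300 230 270 130 270 150 190 50 190 230 270 130 270 230 270 130 270 230 270 190 270 230 270 130 270 230 270 190 270 190 230 90 230 230 270 130 270 100 140 130 140 230 270 130 270 230 270 130 270 230 270 190 270 230 270 130 270 290 270 130 270 260 290 260 270 220 250 220 240 140 230 140 220 220 250 220 240 220 250 220 240 220 250 220 240 220 250 220 240 220 250 220 240 180 270 180 260 220 250 220 240 90 120 90 110 220 250 220 240 220 250 220 240 220 250 220 240 220 250 220 240 220 250 220 240 170 300 110 300 130 270 80 270 50 190 130 190 130 270 80 270 130 270 80 270 190 270 80 270 130 270 80 270 190 270 80 270 90 230 170 230 130 270 80 270 130 140 210 140 130 270 80 270 130 270 80 270 190 270 80 270 130 270 80 270 130 270 210 270 260 270 260 240 220 240 220 150 140 220 140 70 220 240 220 150 220 240 220 150 220 240 220 150 220 240 220 150 220 240 220 150 180 260 180 110 220 240 220 150 90 110 90 150 220 240 220 150 220 240 220 150 220 240 220 150 220 240 220 150 220 240 220 150 160 200 70 200 200 240 100 240 60 100 -30 100 200 240 100 240 200 240 100 240 200 240 160 240 200 240 100 240 200 240 160 240 230 270 130 270 200 240 100 240 70 110 100 110 200 240 100 240 200 240 100 240 200 240 160 240 200 240 100 240 260 240 100 240 160 190 160 170 190 220 190 210 60 150 60 130 190 220 190 210 190 220 190 210 190 220 190 210 190 220 190 210 190 220 190 210 220 310 220 300 190 220 190 210 60 90 60 80 190 220 190 210 190 220 190 210 190 220 190 210 190 220 190 210 190 220 190 210 70 200 10 200 100 240 50 240 -30 100 40 100 100 240 50 240 100 240 50 240 160 240 50 240 100 240 50 240 160 240 50 240 130 270 210 270 100 240 50 240 100 110 180 110 100 240 50 240 100 240 50 240 160 240 50 240 100 240 50 240 100 240 180 240 160 170 160 140 190 210 190 120 60 130 60 -10 190 210 190 120 190 210 190 120 190 210 190 120 190 210 190 120 190 210 190 120 220 300 220 150 190 210 190 120 60 80 60 120 190 210 190 120 190 210 190 120 190 210 190 120 190 210 190 120 190 210 190 120 200 240 100 240 170 210 80 210 70 110 -20 110 170 210 80 210 180 220 90 220 180 220 140 220 180 220 90 220 180 220 140 220 140 180 50 180 170 210 80 210 20 60 60 60 170 210 80 210 180 220 90 220 180 220 140 220 180 220 90 220 150 130 0 130 190 220 190 210 170 200 170 180 70 160 70 140 170 200 170 180 180 210 180 190 170 200 170 190 180 210 180 190 170 200 170 190 140 230 140 210 170 200 170 180 20 50 20 30 170 200 170 180 180 210 180 190 170 200 170 190 180 210 180 190 80 110 80 100 100 240 50 240 80 210 20 210 -20 110 50 110 80 210 20 210 90 220 30 220 140 220 30 220 90 220 30 220 140 220 30 220 50 180 120 180 80 210 20 210 60 60 130 60 80 210 20 210 90 220 30 220 140 220 30 220 90 220 30 220 0 130 70 130 190 210 190 180 170 180 170 90 70 140 70 0 170 180 170 90 180 190 180 100 170 190 170 100 180 190 180 100 170 190 170 100 140 210 140 60 170 180 170 90 20 30 20 70 170 180 170 90 180 190 180 100 170 190 170 100 180 190 180 100 80 100 80 10 200 240 100 240 150 190 60 190 90 130 0 130 150 190 60 190 200 240 100 240 200 240 160 240 200 240 100 240 200 240 160 240 100 140 10 140 150 190 60 190 40 80 80 80 150 190 60 190 200 240 100 240 170 210 130 210 200 240 100 240 170 150 20 150 190 220 190 210 150 180 150 160 90 180 90 160 150 180 150 160 190 220 190 210 190 220 190 210 190 220 190 210 190 220 190 210 100 190 100 170 150 180 150 160 40 70 40 50 150 180 150 160 190 220 190 210 160 190 160 180 190 220 190 210 110 140 110 120 100 240 50 240 60 190 0 190 0 130 70 130 60 190 0 190 100 240 50 240 160 240 50 240 100 240 50 240 160 240 50 240 10 140 80 140 60 190 0 190 80 80 150 80 60 190 0 190 100 240 50 240 130 210 20 210 100 240 50 240 20 150 90 150 190 210 190 180 150 160 150 70 90 160 90 10 150 160 150 70 190 210 190 120 190 210 190 120 190 210 190 120 190 210 190 120 100 170 100 20 150 160 150 70 40 50 40 90 150 160 150 70 190 210 190 120 160 180 160 90 190 210 190 120 110 120 110 30 130 100 40 100 130 110 70 100 -20 70 -50 10 130 100 -10 100 60 50 30 140 220 190 70 130 170 140 30 140 140 110 50 110 0 -100 -70 10 130 100 -10 100 -10 -50 -30 -50 130 100 -10 100 170 140 30 140 140 110 60 110 170 140 30 140 140 30 140 20 110 110 110 110 100 100 100 110 -40 70 10 80 100 100 100 110 150 150 150 150 130 130 130 140 150 150 150 150 120 120 120 120 -70 -60 10 80 100 100 100 110 -40 -40 -40 -50 100 100 100 110 150 150 150 150 120 120 120 120 150 150 150 150 30 30 30 30 -30 100 -30 100 -70 100 -40 100 -170 10 -30 10 -70 100 -40 100 10 140 -30 140 70 130 -10 130 -30 140 10 140 0 110 -60 110 -160 10 0 10 -70 100 -40 100 -90 -50 80 -50 -70 100 -40 100 -30 140 10 140 0 110 20 110 -30 140 10 140 50 20 70 20 110 110 110 150 100 100 100 -20 10 70 10 90 100 100 100 30 150 150 150 0 130 130 130 -10 150 150 150 70 120 120 120 40 10 70 10 90 100 100 100 30 -40 20 -40 140 100 100 100 30 150 150 150 70 120 170 120 20 150 150 150 70 30 30 30 -60 150 120 10 120 120 90 -10 90 -50 -80 -190 -80 120 90 -10 90 120 90 -20 90 120 90 50 90 120 90 -20 90 120 90 50 90 10 -20 -130 -20 120 90 -10 90 -20 -50 -20 -50 120 90 -10 90 120 90 -20 90 130 100 50 100 120 90 -20 90 110 20 -90 20 120 120 120 130 100 100 100 100 -80 -20 -80 -10 100 100 100 100 90 90 90 100 100 100 100 100 90 90 90 100 100 100 100 100 -10 50 -10 50 100 100 100 100 -40 -40 -40 -40 100 100 100 100 90 90 90 100 100 100 100 110 90 90 90 100 20 20 20 30 -50 120 -20 120 -80 90 -40 90 -260 -80 -90 -80 -80 90 -40 90 -80 90 -50 90 -20 90 -40 90 -80 90 -50 90 -20 90 -40 90 -190 -20 -20 -20 -80 90 -40 90 -90 -50 80 -50 -80 90 -40 90 -80 90 -50 90 -10 100 -40 100 -80 90 -50 90 -150 20 10 20 120 120 120 110 100 100 100 20 -80 -20 -80 -150 100 100 100 20 90 90 90 20 100 100 100 20 90 90 90 20 100 100 100 20 -10 50 -10 -90 100 100 100 20 -40 -40 -40 10 100 100 100 20 90 90 90 20 100 100 100 30 90 90 90 20 20 20 20 -50 280 250 140 250 240 210 100 210 160 130 20 130 240 210 100 210 240 210 100 210 240 210 160 210 240 210 100 210 240 210 160 210 200 170 60 170 240 210 100 210 110 80 100 80 240 210 100 210 240 210 100 210 240 210 160 210 240 210 100 210 300 210 100 210 250 250 250 260 220 220 220 220 140 200 140 200 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 180 240 180 240 220 220 220 220 90 90 90 90 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 220 70 250 110 250 40 210 80 210 -40 130 130 130 40 210 80 210 40 210 80 210 100 210 80 210 40 210 80 210 100 210 80 210 0 170 170 170 40 210 80 210 40 80 210 80 40 210 80 210 40 210 80 210 100 210 80 210 40 210 80 210 40 210 210 210 250 250 250 240 220 220 220 140 140 200 140 60 220 220 220 140 220 220 220 140 220 220 220 140 220 220 220 140 220 220 220 140 180 240 180 100 220 220 220 140 90 90 90 140 220 220 220 140 220 220 220 140 220 220 220 140 220 220 220 140 220 220 220 140 190 150 40 150 210 180 70 180 80 50 -60 50 210 180 70 180 210 180 70 180 210 180 130 180 210 180 70 180 210 180 130 180 240 210 100 210 210 180 70 180 80 50 70 50 210 180 70 180 210 180 70 180 210 180 130 180 210 180 70 180 270 180 70 180 150 150 150 160 190 190 190 190 50 110 50 120 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 220 280 220 280 190 190 190 190 60 60 60 60 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -20 150 10 150 10 180 50 180 -120 50 40 50 10 180 50 180 10 180 50 180 70 180 50 180 10 180 50 180 70 180 50 180 40 210 210 210 10 180 50 180 10 50 180 50 10 180 50 180 10 180 50 180 70 180 50 180 10 180 50 180 10 180 180 180 150 150 150 140 190 190 190 110 50 110 50 -20 190 190 190 110 190 190 190 110 190 190 190 110 190 190 190 110 190 190 190 110 220 280 220 140 190 190 190 110 60 60 60 110 190 190 190 110 190 190 190 110 190 190 190 110 190 190 190 110 190 190 190 110 210 180 70 180 190 160 50 160 90 60 -50 60 190 160 50 160 200 170 60 170 190 160 110 160 200 170 60 170 190 160 110 160 160 130 20 130 190 160 50 160 40 10 30 10 190 160 50 160 200 170 60 170 190 160 110 160 200 170 60 170 160 70 -30 70 190 190 190 190 160 160 160 170 60 120 60 130 160 160 160 170 170 170 170 180 170 170 170 170 170 170 170 180 170 170 170 170 130 190 130 200 160 160 160 170 10 10 10 20 160 160 160 170 170 170 170 180 170 170 170 170 170 170 170 180 80 80 80 80 10 180 50 180 -10 160 20 160 -110 60 50 60 -10 160 20 160 0 170 30 170 50 160 30 160 0 170 30 170 50 160 30 160 -40 130 120 130 -10 160 20 160 -30 10 130 10 -10 160 20 160 0 170 30 170 50 160 30 160 0 170 30 170 -100 70 70 70 190 190 190 170 160 160 160 90 60 120 60 -10 160 160 160 90 170 170 170 100 170 170 170 90 170 170 170 100 170 170 170 90 130 190 130 60 160 160 160 90 10 10 10 70 160 160 160 90 170 170 170 100 170 170 170 90 170 170 170 100 80 80 80 0 210 180 70 180 170 140 30 140 110 80 -30 80 170 140 30 140 210 180 70 180 210 180 130 180 210 180 70 180 210 180 130 180 120 90 -20 90 170 140 30 140 60 30 50 30 170 140 30 140 210 180 70 180 180 150 100 150 210 180 70 180 190 100 -10 100 190 190 190 190 140 140 140 150 80 140 80 150 140 140 140 150 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 90 150 90 160 140 140 140 150 30 30 30 40 140 140 140 150 190 190 190 190 160 160 160 160 190 190 190 190 100 100 100 110 10 180 50 180 -30 140 0 140 -90 80 70 80 -30 140 0 140 10 180 50 180 70 180 50 180 10 180 50 180 70 180 50 180 -80 90 80 90 -30 140 0 140 -10 30 150 30 -30 140 0 140 10 180 50 180 40 150 20 150 10 180 50 180 -70 100 90 100 190 190 190 170 140 140 140 70 80 140 80 10 140 140 140 70 190 190 190 110 190 190 190 110 190 190 190 110 190 190 190 110 90 150 90 20 140 140 140 70 30 30 30 90 140 140 140 70 190 190 190 110 160 160 160 80 190 190 190 110 100 100 100 30 270 230 190 230 260 220 180 220 170 130 90 130 260 220 180 220 300 270 230 270 290 250 270 250 300 270 230 270 270 240 260 240 170 130 90 130 260 220 180 220 110 80 170 80 260 220 180 220 300 270 230 270 270 240 260 240 300 270 230 270 240 150 110 150 230 230 230 230 220 220 220 220 130 190 130 190 220 220 220 220 270 270 270 270 250 250 250 250 270 270 270 270 240 240 240 240 130 190 130 190 220 220 220 220 80 80 80 80 220 220 220 220 270 270 270 270 240 240 240 240 270 270 270 270 150 150 150 150 150 230 100 230 140 220 90 220 50 130 130 130 140 220 90 220 190 270 140 270 230 250 120 250 190 270 140 270 220 240 110 240 50 130 130 130 140 220 90 220 130 80 210 80 140 220 90 220 190 270 140 270 220 240 110 240 190 270 140 270 70 150 150 150 230 230 230 290 220 220 220 220 130 190 130 130 220 220 220 220 270 270 270 270 250 250 250 250 270 270 270 270 240 240 240 240 130 190 130 130 220 220 220 220 80 80 80 210 220 220 220 220 270 270 270 270 240 240 240 240 270 270 270 270 150 150 150 150 280 240 200 240 250 220 180 220 70 40 0 40 250 220 180 220 250 210 170 210 250 220 240 220 250 210 170 210 250 220 240 220 140 100 60 100 250 220 180 220 110 80 170 80 250 220 180 220 250 210 170 210 260 220 240 220 250 210 170 210 240 140 100 140 240 240 240 240 220 220 220 220 40 100 40 100 220 220 220 220 210 210 210 210 220 220 220 220 210 210 210 210 220 220 220 220 100 160 100 160 220 220 220 220 80 80 80 80 220 220 220 220 210 210 210 210 220 220 220 220 210 210 210 210 140 140 140 140 160 240 110 240 140 220 90 220 -40 40 40 40 140 220 90 220 130 210 80 210 200 220 90 220 130 210 80 210 200 220 90 220 20 100 100 100 140 220 90 220 130 80 210 80 140 220 90 220 130 210 80 210 200 220 90 220 130 210 80 210 60 140 140 140 240 240 240 300 220 220 220 220 40 100 40 40 220 220 220 220 210 210 210 210 220 220 220 220 210 210 210 210 220 220 220 220 100 160 100 100 220 220 220 220 80 80 80 210 220 220 220 220 210 210 210 210 220 220 220 220 210 210 210 210 140 140 140 140 410 370 330 370 370 340 300 340 290 260 220 260 370 340 300 340 370 340 300 340 370 340 360 340 370 340 300 340 370 340 360 340 330 300 260 300 370 340 300 340 240 210 300 210 370 340 300 340 370 340 300 340 370 340 360 340 370 340 300 340 430 340 300 340 370 370 370 370 340 340 340 340 260 320 260 320 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 300 360 300 360 340 340 340 340 210 210 210 210 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 290 370 240 370 260 340 210 340 180 260 260 260 260 340 210 340 260 340 210 340 320 340 210 340 260 340 210 340 320 340 210 340 220 300 300 300 260 340 210 340 260 210 340 210 260 340 210 340 260 340 210 340 320 340 210 340 260 340 210 340 260 340 340 340 370 370 370 430 340 340 340 340 260 320 260 260 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 300 360 300 300 340 340 340 340 210 210 210 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 340 360 270 360 270 340 310 270 310 220 170 130 170 340 310 270 310 340 310 270 310 340 310 330 310 340 310 270 310 340 310 330 310 370 340 300 340 340 310 270 310 210 180 270 180 340 310 270 310 340 310 270 310 340 310 330 310 340 310 270 310 400 310 270 310 270 270 270 270 310 310 310 310 170 230 170 230 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 340 400 340 400 310 310 310 310 180 180 180 180 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 190 270 140 270 230 310 180 310 20 170 170 170 230 310 180 310 230 310 180 310 290 310 180 310 230 310 180 310 290 310 180 310 260 340 340 340 230 310 180 310 230 180 310 180 230 310 180 310 230 310 180 310 290 310 180 310 230 310 180 310 230 310 310 310 270 270 270 330 310 310 310 310 170 230 170 170 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 340 400 340 340 310 310 310 310 180 180 180 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 340 310 270 310 320 280 240 280 220 180 140 180 320 280 240 280 330 290 250 290 320 290 310 290 330 290 250 290 320 290 310 290 290 250 210 250 320 280 240 280 170 130 220 130 320 280 240 280 330 290 250 290 320 290 310 290 330 290 250 290 290 200 160 200 310 310 310 310 280 280 280 280 180 240 180 240 280 280 280 280 290 290 290 290 290 290 290 290 290 290 290 290 290 290 290 290 250 310 250 310 280 280 280 280 130 130 130 130 280 280 280 280 290 290 290 290 290 290 290 290 290 290 290 290 200 200 200 200 230 310 180 310 200 280 150 280 100 180 180 180 200 280 150 280 210 290 160 290 270 290 160 290 210 290 160 290 270 290 160 290 170 250 250 250 200 280 150 280 180 130 260 130 200 280 150 280 210 290 160 290 270 290 160 290 210 290 160 290 120 200 200 200 310 310 310 370 280 280 280 280 180 240 180 180 280 280 280 280 290 290 290 290 290 290 290 290 290 290 290 290 290 290 290 290 250 310 250 250 280 280 280 280 130 130 130 260 280 280 280 280 290 290 290 290 290 290 290 290 290 290 290 290 200 200 200 200 340 310 270 310 300 260 220 260 240 200 160 200 300 260 220 260 340 310 270 310 340 310 330 310 340 310 270 310 340 310 330 310 250 210 170 210 300 260 220 260 190 150 240 150 300 260 220 260 340 310 270 310 310 280 300 280 340 310 270 310 320 220 180 220 310 310 310 310 260 260 260 260 200 260 200 260 260 260 260 260 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 210 270 210 270 260 260 260 260 150 150 150 150 260 260 260 260 310 310 310 310 280 280 280 280 310 310 310 310 220 220 220 220 230 310 180 310 180 260 130 260 120 200 200 200 180 260 130 260 230 310 180 310 290 310 180 310 230 310 180 310 290 310 180 310 130 210 210 210 180 260 130 260 200 150 280 150 180 260 130 260 230 310 180 310 260 280 150 280 230 310 180 310 140 220 220 220 310 310 310 370 260 260 260 260 200 260 200 200 260 260 260 260 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 210 270 210 210 260 260 260 260 150 150 150 280 260 260 260 260 310 310 310 310 280 280 280 280 310 310 310 310 220 220 220 220 160 200 230 200 160 190 220 190 70 100 130 100 160 190 220 190 200 240 270 240 190 220 310 220 200 240 270 240 170 210 300 210 70 100 130 100 160 190 220 190 10 50 210 50 160 190 220 190 200 240 270 240 170 210 300 210 200 240 270 240 140 120 150 120 200 200 200 200 190 190 190 190 100 160 100 160 190 190 190 190 240 240 240 240 220 220 220 220 240 240 240 240 210 210 210 210 100 160 100 160 190 190 190 190 50 50 50 50 190 190 190 190 240 240 240 240 210 210 210 210 240 240 240 240 120 120 120 120 60 200 70 200 60 190 60 190 -30 100 100 100 60 190 60 190 100 240 110 240 150 220 90 220 100 240 110 240 130 210 80 210 -30 100 100 100 60 190 60 190 40 50 180 50 60 190 60 190 100 240 110 240 130 210 80 210 100 240 110 240 -10 120 120 120 200 200 200 260 190 190 190 190 100 160 100 100 190 190 190 190 240 240 240 240 220 220 220 220 240 240 240 240 210 210 210 210 100 160 100 100 190 190 190 190 50 50 50 180 190 190 190 190 240 240 240 240 210 210 210 210 240 240 240 240 120 120 120 120 190 210 240 210 150 190 220 190 -20 10 40 10 150 190 220 190 150 180 210 180 150 190 280 190 150 180 210 180 150 190 280 190 40 70 100 70 150 190 220 190 10 50 210 50 150 190 220 190 150 180 210 180 160 190 280 190 150 180 210 180 140 110 140 110 210 210 210 210 190 190 190 190 10 70 10 70 190 190 190 190 180 180 180 180 190 190 190 190 180 180 180 180 190 190 190 190 70 130 70 130 190 190 190 190 50 50 50 50 190 190 190 190 180 180 180 180 190 190 190 190 180 180 180 180 110 110 110 110 80 210 80 210 50 190 60 190 -120 10 10 10 50 190 60 190 50 180 50 180 110 190 60 190 50 180 50 180 110 190 60 190 -60 70 70 70 50 190 60 190 40 50 180 50 50 190 60 190 50 180 50 180 120 190 60 190 50 180 50 180 -20 110 110 110 210 210 210 270 190 190 190 190 10 70 10 10 190 190 190 190 180 180 180 180 190 190 190 190 180 180 180 180 190 190 190 190 70 130 70 70 190 190 190 190 50 50 50 180 190 190 190 190 180 180 180 180 190 190 190 190 180 180 180 180 110 110 110 110 360 340 370 340 270 310 340 310 190 230 260 230 270 310 340 310 270 310 340 310 270 310 400 310 270 310 340 310 270 310 400 310 360 270 300 270 270 310 340 310 140 180 340 180 270 310 340 310 270 310 340 310 270 310 400 310 270 310 340 310 330 310 340 310 340 340 340 340 310 310 310 310 230 290 230 290 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 270 330 270 330 310 310 310 310 180 180 180 180 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 220 340 210 340 170 310 180 310 20 230 230 230 170 310 180 310 170 310 180 310 230 310 180 310 170 310 180 310 230 310 180 310 130 270 270 270 170 310 180 310 170 180 310 180 170 310 180 310 170 310 180 310 230 310 180 310 170 310 180 310 170 310 310 310 340 340 340 400 310 310 310 310 230 290 230 230 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 270 330 270 270 310 310 310 310 180 180 180 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 310 210 240 270 240 240 280 310 280 110 140 170 140 240 280 310 280 240 280 310 280 240 280 370 280 240 280 310 280 240 280 370 280 270 310 340 310 240 280 310 280 110 150 310 150 240 280 310 280 240 280 310 280 240 280 370 280 240 280 310 280 300 280 310 280 240 240 240 240 280 280 280 280 140 200 140 200 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 310 370 310 370 280 280 280 280 150 150 150 150 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 110 240 110 240 140 280 150 280 10 140 140 140 140 280 150 280 140 280 150 280 200 280 150 280 140 280 150 280 200 280 150 280 170 310 310 310 140 280 150 280 140 150 280 150 140 280 150 280 140 280 150 280 200 280 150 280 140 280 150 280 140 280 280 280 240 240 240 300 280 280 280 280 140 200 140 140 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 310 370 310 310 280 280 280 280 150 150 150 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 240 280 310 280 220 250 280 250 120 150 180 150 220 250 280 250 230 260 290 260 220 260 350 260 230 260 290 260 220 260 350 260 190 220 250 220 220 250 280 250 70 100 260 100 220 250 280 250 230 260 290 260 220 260 350 260 230 260 290 260 190 170 200 170 280 280 280 280 250 250 250 250 150 210 150 210 250 250 250 250 260 260 260 260 260 260 260 260 260 260 260 260 260 260 260 260 220 280 220 280 250 250 250 250 100 100 100 100 250 250 250 250 260 260 260 260 260 260 260 260 260 260 260 260 170 170 170 170 140 280 150 280 120 250 120 250 20 150 150 150 120 250 120 250 130 260 130 260 180 260 130 260 130 260 130 260 180 260 130 260 90 220 220 220 120 250 120 250 100 100 230 100 120 250 120 250 130 260 130 260 180 260 130 260 130 260 130 260 30 170 170 170 280 280 280 340 250 250 250 250 150 210 150 150 250 250 250 250 260 260 260 260 260 260 260 260 260 260 260 260 260 260 260 260 220 280 220 220 250 250 250 250 100 100 100 230 250 250 250 250 260 260 260 260 260 260 260 260 260 260 260 260 170 170 170 170 240 280 310 280 200 230 260 230 140 170 200 170 200 230 260 230 240 280 310 280 240 280 370 280 240 280 310 280 240 280 370 280 150 180 210 180 200 230 260 230 90 120 280 120 200 230 260 230 240 280 310 280 210 250 340 250 240 280 310 280 220 190 220 190 280 280 280 280 230 230 230 230 170 230 170 230 230 230 230 230 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 180 240 180 240 230 230 230 230 120 120 120 120 230 230 230 230 280 280 280 280 250 250 250 250 280 280 280 280 190 190 190 190 140 280 150 280 100 230 100 230 40 170 170 170 100 230 100 230 140 280 150 280 200 280 150 280 140 280 150 280 200 280 150 280 50 180 180 180 100 230 100 230 120 120 250 120 100 230 100 230 140 280 150 280 170 250 120 250 140 280 150 280 60 190 190 190 280 280 280 340 230 230 230 230 170 230 170 170 230 230 230 230 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 280 180 240 180 180 230 230 230 230 120 120 120 250 230 230 230 230 280 280 280 280 250 250 250 250 280 280 280 280 190 190 190 190 200 180 140 180 190 180 140 180 100 90 50 90 190 180 140 180 240 220 180 220 220 210 230 210 240 220 180 220 210 190 210 190 100 90 50 90 190 180 140 180 50 30 120 30 190 180 140 180 240 220 180 220 210 190 210 190 240 220 180 220 180 100 60 100 170 180 170 180 170 170 170 170 80 140 80 140 170 170 170 170 210 220 210 220 200 200 200 200 210 220 210 220 180 190 180 190 80 140 80 140 170 170 170 170 20 30 20 30 170 170 170 170 210 220 210 220 180 190 180 190 210 220 210 220 90 100 90 100 70 180 20 180 70 180 20 180 -20 90 60 90 70 180 20 180 110 220 60 220 160 210 50 210 110 220 60 220 140 190 30 190 -20 90 60 90 70 180 20 180 50 30 130 30 70 180 20 180 110 220 60 220 140 190 30 190 110 220 60 220 0 100 70 100 170 180 170 150 170 170 170 80 80 140 80 0 170 170 170 80 210 220 210 130 200 200 200 110 210 220 210 130 180 190 180 100 80 140 80 0 170 170 170 80 20 30 20 70 170 170 170 80 210 220 210 130 180 190 180 100 210 220 210 130 90 100 90 10 210 200 160 200 190 170 130 170 10 0 -40 0 190 170 130 170 180 170 130 170 190 170 190 170 180 170 130 170 190 170 190 170 70 60 20 60 190 170 130 170 50 30 120 30 190 170 130 170 180 170 130 170 190 180 200 180 180 170 130 170 170 100 60 100 190 190 190 190 160 170 160 170 -10 50 -10 50 160 170 160 170 160 160 160 160 160 170 160 170 160 160 160 160 160 170 160 170 50 110 50 110 160 170 160 170 20 30 20 30 160 170 160 170 160 160 160 160 170 170 170 170 160 160 160 160 90 90 90 90 90 200 40 200 60 170 10 170 -110 0 -30 0 60 170 10 170 60 170 10 170 120 170 10 170 60 170 10 170 120 170 10 170 -50 60 30 60 60 170 10 170 50 30 130 30 60 170 10 170 60 170 10 170 130 180 20 180 60 170 10 170 -10 100 70 100 190 190 190 160 160 170 160 80 -10 50 -10 -100 160 170 160 80 160 160 160 70 160 170 160 80 160 160 160 70 160 170 160 80 50 110 50 -30 160 170 160 80 20 30 20 70 160 170 160 80 160 160 160 70 170 170 170 80 160 160 160 70 90 90 90 0 340 330 290 330 310 290 250 290 230 210 170 210 310 290 250 290 310 290 250 290 310 290 310 290 310 290 250 290 310 290 310 290 270 250 210 250 310 290 250 290 180 160 250 160 310 290 250 290 310 290 250 290 310 290 310 290 310 290 250 290 370 290 250 290 320 320 320 320 280 290 280 290 200 270 200 270 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 240 310 240 310 280 290 280 290 150 160 150 160 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 280 290 220 330 170 330 180 290 130 290 100 210 180 210 180 290 130 290 180 290 130 290 240 290 130 290 180 290 130 290 240 290 130 290 140 250 220 250 180 290 130 290 180 160 260 160 180 290 130 290 180 290 130 290 240 290 130 290 180 290 130 290 180 290 260 290 320 320 320 290 280 290 280 200 200 270 200 120 280 290 280 200 280 290 280 200 280 290 280 200 280 290 280 200 280 290 280 200 240 310 240 160 280 290 280 200 150 160 150 200 280 290 280 200 280 290 280 200 280 290 280 200 280 290 280 200 280 290 280 200 240 230 190 230 280 260 220 260 140 130 90 130 280 260 220 260 280 260 220 260 280 260 280 260 280 260 220 260 280 260 280 260 310 290 250 290 280 260 220 260 150 130 220 130 280 260 220 260 280 260 220 260 280 260 280 260 280 260 220 260 340 260 220 260 220 220 220 220 250 260 250 260 120 180 120 180 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 280 350 280 350 250 260 250 260 120 130 120 130 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 120 230 70 230 150 260 100 260 20 130 100 130 150 260 100 260 150 260 100 260 210 260 100 260 150 260 100 260 210 260 100 260 180 290 260 290 150 260 100 260 150 130 230 130 150 260 100 260 150 260 100 260 210 260 100 260 150 260 100 260 150 260 230 260 220 220 220 190 250 260 250 170 120 180 120 30 250 260 250 170 250 260 250 170 250 260 250 170 250 260 250 170 250 260 250 170 280 350 280 200 250 260 250 170 120 130 120 170 250 260 250 170 250 260 250 170 250 260 250 170 250 260 250 170 250 260 250 170 280 260 220 260 250 240 200 240 150 140 100 140 250 240 200 240 260 250 210 250 260 240 260 240 260 250 210 250 260 240 260 240 220 210 170 210 250 240 200 240 100 90 180 90 250 240 200 240 260 250 210 250 260 240 260 240 260 250 210 250 230 150 110 150 250 260 250 260 230 230 230 230 130 190 130 190 230 230 230 230 240 240 240 240 230 240 230 240 240 240 240 240 230 240 230 240 200 260 200 260 230 230 230 230 80 80 80 80 230 230 230 230 240 240 240 240 230 240 230 240 240 240 240 240 140 150 140 150 150 260 100 260 130 240 80 240 30 140 110 140 130 240 80 240 140 250 90 250 190 240 80 240 140 250 90 250 190 240 80 240 100 210 180 210 130 240 80 240 110 90 190 90 130 240 80 240 140 250 90 250 190 240 80 240 140 250 90 250 40 150 120 150 250 260 250 230 230 230 230 140 130 190 130 40 230 230 230 140 240 240 240 150 230 240 230 150 240 240 240 150 230 240 230 150 200 260 200 110 230 230 230 140 80 80 80 120 230 230 230 140 240 240 240 150 230 240 230 150 240 240 240 150 140 150 140 60 280 260 220 260 230 220 180 220 170 160 120 160 230 220 180 220 280 260 220 260 280 260 280 260 280 260 220 260 280 260 280 260 180 170 130 170 230 220 180 220 120 110 200 110 230 220 180 220 280 260 220 260 250 230 250 230 280 260 220 260 250 180 140 180 250 260 250 260 210 210 210 210 150 210 150 210 210 210 210 210 250 260 250 260 250 260 250 260 250 260 250 260 250 260 250 260 160 220 160 220 210 210 210 210 100 100 100 100 210 210 210 210 250 260 250 260 220 230 220 230 250 260 250 260 170 170 170 170 150 260 100 260 110 220 60 220 50 160 130 160 110 220 60 220 150 260 100 260 210 260 100 260 150 260 100 260 210 260 100 260 60 170 140 170 110 220 60 220 130 110 210 110 110 220 60 220 150 260 100 260 180 230 70 230 150 260 100 260 70 180 150 180 250 260 250 230 210 210 210 120 150 210 150 60 210 210 210 120 250 260 250 170 250 260 250 170 250 260 250 170 250 260 250 170 160 220 160 70 210 210 210 120 100 100 100 140 210 210 210 120 250 260 250 170 220 230 220 140 250 260 250 170 170 170 170 80 200 200 100 200 190 190 100 190 100 100 10 100 190 190 100 190 240 240 140 240 220 220 190 220 240 240 140 240 210 210 170 210 100 100 10 100 190 190 100 190 50 50 80 50 190 190 100 190 240 240 140 240 210 210 170 210 240 240 140 240 180 120 20 120 150 200 150 170 150 190 150 160 60 160 60 130 150 190 150 160 190 240 190 210 180 220 180 190 190 240 190 210 160 210 160 180 60 160 60 130 150 190 150 160 0 50 0 20 150 190 150 160 190 240 190 210 160 210 160 180 190 240 190 210 70 120 70 90 90 200 40 200 90 190 40 190 0 100 80 100 90 190 40 190 130 240 80 240 180 220 70 220 130 240 80 240 160 210 50 210 0 100 80 100 90 190 40 190 70 50 150 50 90 190 40 190 130 240 80 240 160 210 50 210 130 240 80 240 10 120 90 120 150 200 150 170 150 190 150 110 60 160 60 20 150 190 150 110 190 240 190 150 180 220 180 140 190 240 190 150 160 210 160 120 60 160 60 20 150 190 150 110 0 50 0 90 150 190 150 110 190 240 190 150 160 210 160 120 190 240 190 150 70 120 70 30 210 210 120 210 190 190 90 190 10 10 -80 10 190 190 90 190 180 180 90 180 190 190 150 190 180 180 90 180 190 190 150 190 70 70 -20 70 190 190 90 190 50 50 80 50 190 190 90 190 180 180 90 180 190 190 160 190 180 180 90 180 170 110 20 110 170 210 170 180 140 190 140 160 -30 70 -30 40 140 190 140 160 140 180 140 150 140 190 140 160 140 180 140 150 140 190 140 160 30 130 30 100 140 190 140 160 0 50 0 20 140 190 140 160 140 180 140 150 150 190 150 160 140 180 140 150 70 110 70 80 110 210 60 210 80 190 30 190 -90 10 -10 10 80 190 30 190 80 180 30 180 140 190 30 190 80 180 30 180 140 190 30 190 -30 70 50 70 80 190 30 190 70 50 150 50 80 190 30 190 80 180 30 180 150 190 40 190 80 180 30 180 10 110 90 110 170 210 170 190 140 190 140 100 -30 70 -30 -70 140 190 140 100 140 180 140 100 140 190 140 100 140 180 140 100 140 190 140 100 30 130 30 -10 140 190 140 100 0 50 0 90 140 190 140 100 140 180 140 100 150 190 150 110 140 180 140 100 70 110 70 30 340 340 250 340 310 310 210 310 230 230 130 230 310 310 210 310 310 310 210 310 310 310 270 310 310 310 210 310 310 310 270 310 270 270 170 270 310 310 210 310 180 180 210 180 310 310 210 310 310 310 210 310 310 310 270 310 310 310 210 310 370 310 210 310 300 340 300 310 260 310 260 280 180 290 180 260 260 310 260 280 260 310 260 280 260 310 260 280 260 310 260 280 260 310 260 280 220 330 220 300 260 310 260 280 130 180 130 150 260 310 260 280 260 310 260 280 260 310 260 280 260 310 260 280 260 310 260 280 240 340 190 340 200 310 150 310 120 230 200 230 200 310 150 310 200 310 150 310 260 310 150 310 200 310 150 310 260 310 150 310 160 270 240 270 200 310 150 310 200 180 280 180 200 310 150 310 200 310 150 310 260 310 150 310 200 310 150 310 200 310 280 310 300 340 300 320 260 310 260 220 180 290 180 140 260 310 260 220 260 310 260 220 260 310 260 220 260 310 260 220 260 310 260 220 220 330 220 180 260 310 260 220 130 180 130 220 260 310 260 220 260 310 260 220 260 310 260 220 260 310 260 220 260 310 260 220 240 240 150 240 280 280 180 280 140 140 50 140 280 280 180 280 280 280 180 280 280 280 240 280 280 280 180 280 280 280 240 280 310 310 210 310 280 280 180 280 150 150 180 150 280 280 180 280 280 280 180 280 280 280 240 280 280 280 180 280 340 280 180 280 200 240 200 210 230 280 230 250 100 200 100 170 230 280 230 250 230 280 230 250 230 280 230 250 230 280 230 250 230 280 230 250 260 370 260 340 230 280 230 250 100 150 100 120 230 280 230 250 230 280 230 250 230 280 230 250 230 280 230 250 230 280 230 250 140 240 90 240 170 280 120 280 40 140 120 140 170 280 120 280 170 280 120 280 230 280 120 280 170 280 120 280 230 280 120 280 200 310 280 310 170 280 120 280 170 150 250 150 170 280 120 280 170 280 120 280 230 280 120 280 170 280 120 280 170 280 250 280 200 240 200 220 230 280 230 190 100 200 100 60 230 280 230 190 230 280 230 190 230 280 230 190 230 280 230 190 230 280 230 190 260 370 260 220 230 280 230 190 100 150 100 190 230 280 230 190 230 280 230 190 230 280 230 190 230 280 230 190 230 280 230 190 280 280 180 280 250 250 160 250 150 150 60 150 250 250 160 250 260 260 170 260 260 260 220 260 260 260 170 260 260 260 220 260 220 220 130 220 250 250 160 250 100 100 140 100 250 250 160 250 260 260 170 260 260 260 220 260 260 260 170 260 230 170 70 170 230 280 230 250 210 250 210 220 110 210 110 180 210 250 210 220 220 260 220 230 210 260 210 230 220 260 220 230 210 260 210 230 180 280 180 250 210 250 210 220 60 100 60 70 210 250 210 220 220 260 220 230 210 260 210 230 220 260 220 230 120 170 120 140 170 280 120 280 150 250 100 250 50 150 130 150 150 250 100 250 160 260 110 260 210 260 100 260 160 260 110 260 210 260 100 260 120 220 200 220 150 250 100 250 130 100 210 100 150 250 100 250 160 260 110 260 210 260 100 260 160 260 110 260 60 170 140 170 230 280 230 250 210 250 210 170 110 210 110 70 210 250 210 170 220 260 220 180 210 260 210 170 220 260 220 180 210 260 210 170 180 280 180 140 210 250 210 170 60 100 60 150 210 250 210 170 220 260 220 180 210 260 210 170 220 260 220 180 120 170 120 80 280 280 180 280 230 230 140 230 170 170 80 170 230 230 140 230 280 280 180 280 280 280 240 280 280 280 180 280 280 280 240 280 180 180 90 180 230 230 140 230 120 120 160 120 230 230 140 230 280 280 180 280 250 250 210 250 280 280 180 280 250 190 100 190 230 280 230 250 190 230 190 200 130 230 130 200 190 230 190 200 230 280 230 250 230 280 230 250 230 280 230 250 230 280 230 250 140 240 140 210 190 230 190 200 80 120 80 90 190 230 190 200 230 280 230 250 200 250 200 220 230 280 230 250 150 190 150 160 170 280 120 280 130 230 80 230 70 170 150 170 130 230 80 230 170 280 120 280 230 280 120 280 170 280 120 280 230 280 120 280 80 180 160 180 130 230 80 230 150 120 230 120 130 230 80 230 170 280 120 280 200 250 90 250 170 280 120 280 90 190 170 190 230 280 230 250 190 230 190 150 130 230 130 90 190 230 190 150 230 280 230 190 230 280 230 190 230 280 230 190 230 280 230 190 140 240 140 100 190 230 190 150 80 120 80 170 190 230 190 150 230 280 230 190 200 250 200 160 230 280 230 190 150 190 150 110"
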