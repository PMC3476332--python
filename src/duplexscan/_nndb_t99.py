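"""Turner 1999 RNA nearest-neighbor free-energy tables.

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

NINIO_M = 48
NINIO_MAX = 300
TERM_AU = 50
DUPLEX_INIT = 410
LXC = 107.856

BULGE = "100000 380 280 320 360 400 440 459 470 480 490 500 510 519 527 534 541 548 554 560 565 571 576 580 585 589 594 598 602 605 609"

INTERNAL = "100000 100000 410 510 170 180 200 220 230 240 250 260 270 278 286 294 301 307 313 319 325 330 335 340 345 349 353 357 361 365 369"

STACK = "-240 -330 -210 -140 -210 -210 -330 -340 -250 -150 -220 -240 -210 -250 130 -50 -140 -130 -140 -150 -50 30 -60 -100 -210 -220 -140 -60 -110 -90 -210 -240 -130 -100 -90 -130"

MISMATCH_I = "0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0"

MISMATCH_1N = "0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0"

MISMATCH_23 = "0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -110 0 0 0 0 0 0 0 -70 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0 0 0 0 0 0 0 70 70 -40 70 0 70 70 70 70 0 -40 70 70 70 0 70 70 70 0"

INT11 = "110 110 110 110 110 110 110 40 40 40 110 40 40 40 40 110 40 40 -140 40 110 40 40 40 40 110 110 110 110 110 110 40 -40 40 40 110 30 50 40 50 110 -10 40 -170 40 110 40 0 40 -30 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 40 30 -10 40 110 -40 50 40 0 110 40 40 -170 40 110 40 50 40 -30 110 110 110 110 110 110 80 40 40 40 110 40 40 40 40 110 40 40 -210 40 110 40 40 40 -70 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 100 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 120 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 150 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 110 -100 110 110 110 110 110 110 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 150 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 170 -40 170 170 170 170 170 180"

INT21 = "550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 240 220 160 400 550 210 170 160 400 550 100 60 40 400 550 400 400 400 400 550 550 550 550 550 550 230 220 400 220 550 220 250 400 220 550 400 400 400 400 550 250 190 400 220 550 550 550 550 550 550 170 400 80 400 550 400 400 400 400 550 80 400 220 400 550 400 400 400 400 550 550 550 550 550 550 400 400 400 400 550 400 220 400 130 550 400 400 400 400 550 400 170 400 120 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 230 220 110 400 550 210 170 160 400 550 80 60 40 400 550 400 400 400 400 550 550 550 550 550 550 230 220 400 220 550 220 250 400 220 550 400 400 400 400 550 250 190 400 220 550 550 550 550 550 550 170 400 80 400 550 400 400 400 400 550 80 400 220 400 550 400 400 400 400 550 550 550 550 550 550 400 400 400 400 550 400 220 400 150 550 400 400 400 400 550 400 170 400 120 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 250 220 210 400 550 210 170 160 400 550 120 60 40 400 550 400 400 400 400 550 550 550 550 550 550 230 220 400 220 550 220 250 400 220 550 400 400 400 400 550 250 190 400 220 550 550 550 550 550 550 170 400 80 400 550 400 400 400 400 550 80 400 220 400 550 400 400 400 400 550 550 550 550 550 550 400 400 400 400 550 400 220 400 120 550 400 400 400 400 550 400 170 400 120 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 240 220 160 400 550 210 170 160 400 550 100 60 40 400 550 400 400 400 400 550 550 550 550 550 550 230 220 400 220 550 220 250 400 220 550 400 400 400 400 550 250 190 400 220 550 550 550 550 550 550 170 400 80 400 550 400 400 400 400 550 80 400 220 400 550 400 400 400 400 550 550 550 550 550 550 400 400 400 400 550 400 220 400 130 550 400 400 400 400 550 400 170 400 120 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 320 300 240 480 550 290 250 240 480 550 180 140 120 480 550 480 480 480 480 550 550 550 550 550 550 310 300 480 300 550 300 330 480 300 550 480 480 480 480 550 330 270 480 300 550 550 550 550 550 550 250 480 160 480 550 480 480 480 480 550 160 480 300 480 550 480 480 480 480 550 550 550 550 550 550 480 480 480 480 550 480 300 480 210 550 480 480 480 480 550 480 250 480 200 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 390 370 310 550 550 360 320 310 550 550 250 210 190 550 550 550 550 550 550 550 550 550 550 550 550 380 370 550 370 550 370 400 550 370 550 550 550 550 550 550 400 340 550 370 550 550 550 550 550 550 320 550 230 550 550 550 550 550 550 550 230 550 370 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 550 370 550 280 550 550 550 550 550 550 550 320 550 270"

INT22 = "130 160 30 200 120 150 20 200 30 60 -70 200 200 200 200 200 160 200 60 200 210 180 150 200 200 200 200 200 190 170 130 200 30 60 -70 200 200 200 200 200 100 140 0 200 -40 -110 -60 200 200 200 200 200 190 170 130 200 110 40 90 200 140 80 130 200 120 210 200 190 110 140 200 120 20 150 200 130 200 200 200 200 150 180 200 170 140 170 200 150 200 200 200 200 120 150 200 140 20 150 200 130 200 200 200 200 90 180 200 170 -150 -20 200 -40 200 200 200 200 120 150 200 140 0 130 200 110 30 60 200 50 30 200 100 110 20 200 90 0 -70 200 0 90 200 200 200 200 60 200 140 40 150 200 180 130 200 200 200 200 130 200 170 110 -70 200 0 90 200 200 200 200 0 200 80 90 -60 200 -70 -260 200 200 200 200 130 200 170 110 90 200 90 -110 130 200 120 110 200 190 -40 140 200 120 -150 30 200 130 -60 130 200 200 200 200 200 170 -110 80 200 150 -20 60 200 200 200 200 200 140 -40 50 200 130 -60 130 200 200 200 200 200 170 -70 120 200 -40 -420 -50 200 200 200 200 200 140 -40 50 200 110 -260 110 200 50 -50 -40 50 60 0 200 110 150 -70 200 -30 10 -160 200 200 200 200 200 110 110 -100 200 170 150 -60 200 200 200 200 200 70 50 20 200 40 50 -70 200 200 200 200 200 100 140 0 200 10 -70 -80 200 200 200 200 200 180 150 120 200 -50 -60 -60 200 150 0 90 200 130 220 200 200 100 130 200 120 -70 70 200 40 200 200 200 200 100 190 200 110 100 130 200 120 200 200 200 200 0 30 200 170 70 70 200 100 200 200 200 200 90 180 200 170 -190 -30 200 -70 200 200 200 200 110 140 200 120 -150 -20 200 -30 -20 -10 200 20 -20 200 110 90 -40 200 90 0 -170 200 -90 30 200 200 200 200 70 200 80 -10 110 200 150 100 200 200 200 200 20 200 50 0 -50 200 -20 60 200 200 200 200 0 200 80 90 -90 200 -100 -300 200 200 200 200 120 200 150 100 -130 200 -60 -240 90 200 110 60 200 200 -10 140 200 120 -160 30 200 40 -160 50 200 200 200 200 200 110 -160 30 200 120 -60 30 200 200 200 200 200 20 -160 10 200 50 -60 140 200 200 200 200 200 170 -70 120 200 -70 -440 -100 200 200 200 200 200 120 -50 30 200 -10 -410 10 200 40 -100 60 200 240 100 200 180 210 80 200 80 110 -20 200 200 200 200 200 190 220 90 200 230 210 170 200 200 200 200 200 230 210 170 200 80 110 -20 200 200 200 200 200 130 170 30 200 60 0 40 200 200 200 200 200 230 210 170 200 160 90 140 200 190 130 180 200 190 280 200 270 170 200 200 180 70 200 200 180 200 200 200 200 180 210 200 190 160 190 200 180 200 200 200 200 160 190 200 180 70 200 200 180 200 200 200 200 120 210 200 200 -50 80 200 70 200 200 200 200 160 190 200 180 50 180 200 160 80 110 200 100 100 200 180 180 80 200 150 60 -20 200 50 140 200 200 200 200 90 200 160 70 170 200 210 150 200 200 200 200 170 200 210 150 -20 200 50 140 200 200 200 200 30 200 110 110 40 200 40 -160 200 200 200 200 170 200 210 150 140 200 130 -60 180 200 170 160 200 270 30 220 200 180 -90 90 200 180 -10 180 200 200 200 200 200 190 -80 100 200 180 0 90 200 200 200 200 200 180 0 90 200 180 -10 180 200 200 200 200 200 200 -40 150 200 70 -310 60 200 200 200 200 200 180 0 90 200 160 -210 160 200 100 0 10 200 240 100 200 160 190 60 200 100 130 0 200 200 200 200 200 200 240 100 200 260 240 200 200 200 200 200 200 260 240 200 200 100 130 0 200 200 200 200 200 140 170 40 200 20 -40 0 200 200 200 200 200 230 210 170 200 150 80 130 200 220 150 200 200 190 280 200 270 150 180 200 160 90 220 200 200 200 200 200 200 190 220 200 210 190 220 200 210 200 200 200 200 190 220 200 210 90 220 200 200 200 200 200 200 130 220 200 200 -90 40 200 30 200 200 200 200 160 190 200 180 40 170 200 150 110 140 200 120 100 200 180 180 60 200 130 40 0 200 70 160 200 200 200 200 100 200 180 80 200 200 240 180 200 200 200 200 200 200 240 180 0 200 70 160 200 200 200 200 40 200 110 120 0 200 0 -200 200 200 200 200 170 200 210 150 130 200 120 -70 200 200 190 180 200 270 30 220 200 160 -110 70 200 200 10 190 200 200 200 200 200 210 -70 120 200 210 30 120 200 200 200 200 200 210 30 120 200 200 10 190 200 200 200 200 200 200 -30 150 200 30 -350 20 200 200 200 200 200 180 0 90 200 150 -220 150 200 120 30 30 200 240 100 200 180 210 80 200 80 110 -20 200 200 200 200 200 190 220 90 200 230 210 170 200 200 200 200 200 230 210 170 200 80 110 -20 200 200 200 200 200 130 170 30 200 60 0 40 200 200 200 200 200 230 210 170 200 160 90 140 200 190 130 180 200 190 280 200 270 170 200 200 180 70 200 200 180 200 200 200 200 180 210 200 190 160 190 200 180 200 200 200 200 160 190 200 180 70 200 200 180 200 200 200 200 120 210 200 200 -50 80 200 70 200 200 200 200 160 190 200 180 50 180 200 160 80 110 200 100 100 200 180 180 80 200 150 60 -20 200 50 140 200 200 200 200 90 200 160 70 170 200 210 150 200 200 200 200 170 200 210 150 -20 200 50 140 200 200 200 200 30 200 110 110 40 200 40 -160 200 200 200 200 170 200 210 150 140 200 130 -60 180 200 170 160 200 270 30 220 200 180 -90 90 200 180 -10 180 200 200 200 200 200 190 -80 100 200 180 0 90 200 200 200 200 200 180 0 90 200 180 -10 180 200 200 200 200 200 200 -40 150 200 70 -310 60 200 200 200 200 200 180 0 90 200 160 -210 160 200 100 0 10 200 240 100 200 160 190 60 200 100 130 0 200 200 200 200 200 200 240 100 200 260 240 200 200 200 200 200 200 260 240 200 200 100 130 0 200 200 200 200 200 140 170 40 200 20 -40 0 200 200 200 200 200 230 210 170 200 150 80 130 200 220 150 200 200 190 280 200 270 150 180 200 160 90 220 200 200 200 200 200 200 190 220 200 210 190 220 200 210 200 200 200 200 190 220 200 210 90 220 200 200 200 200 200 200 130 220 200 200 -90 40 200 30 200 200 200 200 160 190 200 180 40 170 200 150 110 140 200 120 100 200 180 180 60 200 130 40 0 200 70 160 200 200 200 200 100 200 180 80 200 200 240 180 200 200 200 200 200 200 240 180 0 200 70 160 200 200 200 200 40 200 110 120 0 200 0 -200 200 200 200 200 170 200 210 150 130 200 120 -70 200 200 190 180 200 270 30 220 200 160 -110 70 200 200 10 190 200 200 200 200 200 210 -70 120 200 210 30 120 200 200 200 200 200 210 30 120 200 200 10 190 200 200 200 200 200 200 -30 150 200 30 -350 20 200 200 200 200 200 180 0 90 200 150 -220 150 200 120 30 30 50 110 40 200 130 100 70 200 -20 70 -50 200 200 200 200 200 60 110 50 200 220 190 70 200 200 200 200 200 200 110 50 200 0 -100 -70 200 200 200 200 200 110 80 -20 200 -10 -160 -60 200 200 200 200 200 200 110 100 200 90 -10 60 200 140 30 140 200 110 170 200 180 100 100 200 110 -40 110 200 120 200 200 200 200 150 150 200 150 130 130 200 140 200 200 200 200 120 120 200 120 -70 -60 200 120 200 200 200 200 90 150 200 150 -160 -60 200 -50 200 200 200 200 120 120 200 120 0 100 200 100 30 30 200 30 -30 200 100 -50 -70 200 90 -150 -170 200 0 -130 200 200 200 200 10 200 140 -60 70 200 180 -20 200 200 200 200 40 200 170 -10 -160 200 0 -60 200 200 200 200 -90 200 80 -60 -160 200 -70 -410 200 200 200 200 40 200 170 -30 30 200 90 -240 50 200 120 10 200 70 10 150 200 0 -190 -20 200 20 -90 90 200 200 200 200 200 50 -70 0 200 30 -30 -10 200 200 200 200 200 20 -70 40 200 20 -80 90 200 200 200 200 200 50 -100 110 200 -160 -440 -100 200 200 200 200 200 170 -70 20 200 0 -300 60 200 10 -100 60 150 120 10 200 120 90 -10 200 -50 -80 -190 200 200 200 200 200 120 90 -20 200 180 90 90 200 200 200 200 200 80 0 -10 200 10 -20 -130 200 200 200 200 200 110 80 -20 200 -70 -200 -130 200 200 200 200 200 190 100 90 200 -30 -160 -90 200 150 20 90 200 120 180 200 190 100 100 200 100 -80 20 200 30 200 200 200 200 90 90 200 100 100 100 200 100 200 200 200 200 0 0 200 0 -10 90 200 90 200 200 200 200 90 150 200 150 -190 -90 200 -90 200 200 200 200 100 100 200 110 -150 -50 200 -50 20 20 200 30 -50 200 110 -30 -80 200 90 -150 -260 200 -90 -150 200 200 200 200 -80 200 80 -160 20 200 150 -50 200 200 200 200 -80 200 50 -150 -190 200 -20 -90 200 200 200 200 -90 200 80 -60 -190 200 -100 -450 200 200 200 200 30 200 150 -50 -150 200 -60 -410 30 200 110 -50 200 80 -70 150 200 0 -190 20 200 -80 -190 30 200 200 200 200 200 0 -200 20 200 0 -90 20 200 200 200 200 200 -100 -190 -70 200 -10 -130 90 200 200 200 200 200 50 -100 110 200 -190 -490 -90 200 200 200 200 200 0 -90 30 200 -150 -450 -50 200 -70 -90 -50 210 180 70 200 190 160 50 200 90 60 -50 200 200 200 200 200 200 170 60 200 240 150 140 200 200 200 200 200 240 150 140 200 90 60 -50 200 200 200 200 200 140 110 0 200 70 -60 10 200 200 200 200 200 240 150 140 200 170 40 110 200 200 70 150 200 190 250 200 250 160 160 200 170 60 160 200 170 200 200 200 200 170 170 200 180 160 160 200 160 200 200 200 200 160 160 200 160 60 160 200 170 200 200 200 200 120 180 200 180 -50 50 200 50 200 200 200 200 160 160 200 160 40 140 200 150 80 80 200 80 10 200 180 40 -10 200 150 -90 -110 200 50 -10 200 200 200 200 0 200 160 -80 80 200 210 10 200 200 200 200 80 200 210 10 -110 200 50 -10 200 200 200 200 -60 200 110 -30 -50 200 40 -310 200 200 200 200 80 200 210 10 50 200 130 -210 80 200 170 10 200 150 0 210 200 60 -130 90 200 70 -50 170 200 200 200 200 200 70 -120 100 200 60 -30 80 200 200 200 200 200 60 -30 80 200 70 -50 170 200 200 200 200 200 80 -70 140 200 -50 -350 50 200 200 200 200 200 60 -30 80 200 50 -250 150 200 -20 -30 0 210 180 70 200 170 140 30 200 110 80 -30 200 200 200 200 200 210 180 70 200 270 180 170 200 200 200 200 200 270 180 170 200 110 80 -30 200 200 200 200 200 150 120 10 200 30 -100 -30 200 200 200 200 200 240 150 140 200 160 30 100 200 230 100 170 200 190 250 200 250 140 140 200 150 80 180 200 190 200 200 200 200 190 190 200 190 190 190 200 190 200 200 200 200 190 190 200 190 80 180 200 190 200 200 200 200 120 180 200 190 -90 10 200 10 200 200 200 200 160 160 200 160 30 130 200 140 100 100 200 110 10 200 180 40 -30 200 130 -110 -90 200 70 10 200 200 200 200 10 200 180 -60 110 200 240 40 200 200 200 200 110 200 240 40 -90 200 70 10 200 200 200 200 -50 200 110 -30 -90 200 0 -350 200 200 200 200 80 200 210 10 40 200 120 -220 110 200 190 30 200 150 0 210 200 40 -150 70 200 90 -30 190 200 200 200 200 200 90 -100 110 200 90 0 110 200 200 200 200 200 90 0 110 200 90 -30 190 200 200 200 200 200 80 -70 150 200 -90 -390 10 200 200 200 200 200 60 -30 80 200 40 -260 140 200 0 -10 30 210 180 70 200 190 160 50 200 90 60 -50 200 200 200 200 200 200 170 60 200 240 150 140 200 200 200 200 200 240 150 140 200 90 60 -50 200 200 200 200 200 140 110 0 200 70 -60 10 200 200 200 200 200 240 150 140 200 170 40 110 200 200 70 150 200 190 250 200 250 160 160 200 170 60 160 200 170 200 200 200 200 170 170 200 180 160 160 200 160 200 200 200 200 160 160 200 160 60 160 200 170 200 200 200 200 120 180 200 180 -50 50 200 50 200 200 200 200 160 160 200 160 40 140 200 150 80 80 200 80 10 200 180 40 -10 200 150 -90 -110 200 50 -10 200 200 200 200 0 200 160 -80 80 200 210 10 200 200 200 200 80 200 210 10 -110 200 50 -10 200 200 200 200 -60 200 110 -30 -50 200 40 -310 200 200 200 200 80 200 210 10 50 200 130 -210 80 200 170 10 200 150 0 210 200 60 -130 90 200 70 -50 170 200 200 200 200 200 70 -120 100 200 60 -30 80 200 200 200 200 200 60 -30 80 200 70 -50 170 200 200 200 200 200 80 -70 140 200 -50 -350 50 200 200 200 200 200 60 -30 80 200 50 -250 150 200 -20 -30 0 210 180 70 200 170 140 30 200 110 80 -30 200 200 200 200 200 210 180 70 200 270 180 170 200 200 200 200 200 270 180 170 200 110 80 -30 200 200 200 200 200 150 120 10 200 30 -100 -30 200 200 200 200 200 240 150 140 200 160 30 100 200 230 100 170 200 190 250 200 250 140 140 200 150 80 180 200 190 200 200 200 200 190 190 200 190 190 190 200 190 200 200 200 200 190 190 200 190 80 180 200 190 200 200 200 200 120 180 200 190 -90 10 200 10 200 200 200 200 160 160 200 160 30 130 200 140 100 100 200 110 10 200 180 40 -30 200 130 -110 -90 200 70 10 200 200 200 200 10 200 180 -60 110 200 240 40 200 200 200 200 110 200 240 40 -90 200 70 10 200 200 200 200 -50 200 110 -30 -90 200 0 -350 200 200 200 200 80 200 210 10 40 200 120 -220 110 200 190 30 200 150 0 210 200 40 -150 70 200 90 -30 190 200 200 200 200 200 90 -100 110 200 90 0 110 200 200 200 200 200 90 0 110 200 90 -30 190 200 200 200 200 200 80 -70 150 200 -90 -390 10 200 200 200 200 200 60 -30 80 200 40 -260 140 200 0 -10 30 200 190 80 200 190 180 70 200 100 90 -20 200 200 200 200 200 240 220 110 200 280 210 200 200 200 200 200 200 270 190 180 200 100 90 -20 200 200 200 200 200 180 160 50 200 30 -80 -10 200 200 200 200 200 270 190 180 200 180 70 140 200 220 100 180 200 180 230 200 230 170 160 200 160 80 170 200 170 200 200 200 200 210 210 200 210 200 190 200 190 200 200 200 200 180 180 200 180 80 170 200 170 200 200 200 200 150 210 200 210 -90 0 200 0 200 200 200 200 180 180 200 180 60 150 200 150 90 90 200 90 80 200 130 160 70 200 120 50 -20 200 30 140 200 200 200 200 110 200 170 90 200 200 210 180 200 200 200 200 180 200 200 160 -20 200 30 140 200 200 200 200 50 200 110 130 -10 200 -40 -210 200 200 200 200 180 200 200 160 140 200 110 -60 180 200 150 160 200 230 60 190 200 160 -50 80 200 170 40 180 200 200 200 200 200 210 0 130 200 190 80 110 200 200 200 200 200 180 70 100 200 170 40 180 200 200 200 200 200 210 40 170 200 0 -310 0 200 200 200 200 200 180 70 100 200 150 -160 160 200 90 60 10 210 200 90 200 190 170 60 200 10 0 -110 200 200 200 200 200 180 170 60 200 250 170 160 200 200 200 200 200 150 70 70 200 70 60 -50 200 200 200 200 200 180 160 50 200 0 -120 -50 200 200 200 200 200 250 180 170 200 40 -80 -10 200 210 100 170 200 190 240 200 240 160 160 200 160 -10 80 200 80 200 200 200 200 160 150 200 150 160 160 200 160 200 200 200 200 60 60 200 60 50 140 200 140 200 200 200 200 150 210 200 210 -130 -30 200 -30 200 200 200 200 170 160 200 160 -90 10 200 10 90 80 200 80 90 200 140 170 60 200 120 40 -110 200 -60 50 200 200 200 200 60 200 110 40 160 200 180 140 200 200 200 200 70 200 80 50 -50 200 0 110 200 200 200 200 50 200 110 130 -50 200 -70 -250 200 200 200 200 170 200 180 150 -10 200 -30 -210 170 200 140 150 200 240 70 200 200 160 -50 80 200 80 -50 80 200 200 200 200 200 150 -60 70 200 160 50 80 200 200 200 200 200 60 -50 -20 200 140 10 150 200 200 200 200 200 210 40 170 200 -30 -350 -30 200 200 200 200 200 160 50 80 200 10 -310 10 200 80 50 0 280 260 150 200 250 240 130 200 150 140 30 200 200 200 200 200 260 250 140 200 310 230 220 200 200 200 200 200 310 230 220 200 150 140 30 200 200 200 200 200 210 190 80 200 130 20 90 200 200 200 200 200 310 230 220 200 230 120 190 200 270 150 220 200 250 310 200 310 230 220 200 220 130 220 200 220 200 200 200 200 240 230 200 230 220 220 200 220 200 200 200 200 220 220 200 220 130 220 200 220 200 200 200 200 180 240 200 240 10 100 200 100 200 200 200 200 220 220 200 220 110 200 200 200 140 140 200 140 150 200 210 230 130 200 180 110 30 200 80 190 200 200 200 200 140 200 190 120 220 200 240 200 200 200 200 200 220 200 240 200 30 200 80 190 200 200 200 200 80 200 140 160 90 200 70 -110 200 200 200 200 220 200 240 200 190 200 160 -10 220 200 200 200 200 310 130 270 200 220 10 140 200 220 90 220 200 200 200 200 200 230 20 150 200 220 100 140 200 200 200 200 200 220 100 140 200 220 90 220 200 200 200 200 200 240 70 200 200 100 -210 110 200 200 200 200 200 220 100 140 200 200 -110 200 200 140 110 60 280 260 150 200 230 220 110 200 170 160 50 200 200 200 200 200 280 260 150 200 340 260 250 200 200 200 200 200 340 260 250 200 170 160 50 200 200 200 200 200 210 200 90 200 100 -20 50 200 200 200 200 200 310 230 220 200 220 110 180 200 290 180 250 200 250 310 200 310 210 200 200 200 150 240 200 240 200 200 200 200 250 250 200 250 250 250 200 250 200 200 200 200 250 250 200 250 150 240 200 240 200 200 200 200 190 240 200 240 -30 70 200 70 200 200 200 200 220 220 200 220 100 190 200 190 170 160 200 160 150 200 210 230 110 200 160 90 50 200 100 210 200 200 200 200 150 200 210 130 250 200 270 230 200 200 200 200 250 200 270 230 50 200 100 210 200 200 200 200 90 200 140 170 50 200 30 -150 200 200 200 200 220 200 240 200 180 200 150 -20 250 200 220 230 200 310 130 270 200 200 -10 120 200 240 110 240 200 200 200 200 200 250 30 170 200 250 130 170 200 200 200 200 200 250 130 170 200 240 110 240 200 200 200 200 200 240 70 200 200 70 -250 70 200 200 200 200 200 220 100 140 200 190 -120 190 200 160 130 80 280 260 150 200 250 240 130 200 150 140 30 200 200 200 200 200 260 250 140 200 310 230 220 200 200 200 200 200 310 230 220 200 150 140 30 200 200 200 200 200 210 190 80 200 130 20 90 200 200 200 200 200 310 230 220 200 230 120 190 200 270 150 220 200 250 310 200 310 230 220 200 220 130 220 200 220 200 200 200 200 240 230 200 230 220 220 200 220 200 200 200 200 220 220 200 220 130 220 200 220 200 200 200 200 180 240 200 240 10 100 200 100 200 200 200 200 220 220 200 220 110 200 200 200 140 140 200 140 150 200 210 230 130 200 180 110 30 200 80 190 200 200 200 200 140 200 190 120 220 200 240 200 200 200 200 200 220 200 240 200 30 200 80 190 200 200 200 200 80 200 140 160 90 200 70 -110 200 200 200 200 220 200 240 200 190 200 160 -10 220 200 200 200 200 310 130 270 200 220 10 140 200 220 90 220 200 200 200 200 200 230 20 150 200 220 100 140 200 200 200 200 200 220 100 140 200 220 90 220 200 200 200 200 200 240 70 200 200 100 -210 110 200 200 200 200 200 220 100 140 200 200 -110 200 200 140 110 60 280 260 150 200 230 220 110 200 170 160 50 200 200 200 200 200 280 260 150 200 340 260 250 200 200 200 200 200 340 260 250 200 170 160 50 200 200 200 200 200 210 200 90 200 100 -20 50 200 200 200 200 200 310 230 220 200 220 110 180 200 290 180 250 200 250 310 200 310 210 200 200 200 150 240 200 240 200 200 200 200 250 250 200 250 250 250 200 250 200 200 200 200 250 250 200 250 150 240 200 240 200 200 200 200 190 240 200 240 -30 70 200 70 200 200 200 200 220 220 200 220 100 190 200 190 170 160 200 160 150 200 210 230 110 200 160 90 50 200 100 210 200 200 200 200 150 200 210 130 250 200 270 230 200 200 200 200 250 200 270 230 50 200 100 210 200 200 200 200 90 200 140 170 50 200 30 -150 200 200 200 200 220 200 240 200 180 200 150 -20 250 200 220 230 200 310 130 270 200 200 -10 120 200 240 110 240 200 200 200 200 200 250 30 170 200 250 130 170 200 200 200 200 200 250 130 170 200 240 110 240 200 200 200 200 200 240 70 200 200 70 -250 70 200 200 200 200 200 220 100 140 200 190 -120 190 200 160 130 80 200 200 100 200 190 190 90 200 100 100 0 200 200 200 200 200 240 240 130 200 280 220 220 200 200 200 200 200 270 210 200 200 100 100 0 200 200 200 200 200 180 180 70 200 30 -70 10 200 200 200 200 200 270 210 200 200 180 80 160 200 220 120 190 200 160 260 200 230 150 190 200 160 60 200 200 170 200 200 200 200 190 240 200 210 180 220 200 190 200 200 200 200 160 210 200 180 60 200 200 170 200 200 200 200 130 240 200 210 -110 30 200 0 200 200 200 200 160 210 200 180 40 180 200 150 70 120 200 90 100 200 140 150 90 200 130 40 0 200 40 130 200 200 200 200 130 200 170 80 220 200 220 170 200 200 200 200 200 200 200 150 0 200 40 130 200 200 200 200 70 200 110 120 10 200 -30 -220 200 200 200 200 200 200 200 150 160 200 120 -70 190 200 150 150 200 260 20 220 200 190 -90 110 200 200 0 200 200 200 200 200 200 240 -40 150 200 220 40 140 200 200 200 200 200 210 30 120 200 200 0 200 200 200 200 200 200 240 0 190 200 30 -350 30 200 200 200 200 200 210 30 120 200 180 -200 180 200 120 20 30 210 210 110 200 190 190 80 200 10 10 -90 200 200 200 200 200 180 180 80 200 250 190 180 200 200 200 200 200 150 90 90 200 70 70 -30 200 200 200 200 200 180 180 70 200 0 -100 -30 200 200 200 200 200 250 190 190 200 40 -60 10 200 210 110 190 200 170 270 200 240 140 190 200 160 -30 110 200 80 200 200 200 200 140 180 200 150 140 190 200 160 200 200 200 200 40 90 200 60 30 170 200 140 200 200 200 200 130 240 200 210 -150 0 200 -30 200 200 200 200 150 190 200 160 -110 40 200 10 70 110 200 80 110 200 150 160 80 200 120 30 -90 200 -50 40 200 200 200 200 80 200 120 30 180 200 180 130 200 200 200 200 90 200 80 40 -30 200 10 100 200 200 200 200 70 200 110 120 -30 200 -70 -260 200 200 200 200 190 200 190 140 10 200 -30 -220 190 200 150 140 200 270 30 230 200 190 -90 100 200 110 -90 110 200 200 200 200 200 180 -100 100 200 190 10 100 200 200 200 200 200 90 -90 0 200 170 -30 170 200 200 200 200 200 240 0 190 200 0 -390 -10 200 200 200 200 200 190 10 110 200 40 -350 30 200 110 10 30 280 280 170 200 250 250 150 200 150 150 50 200 200 200 200 200 260 260 160 200 310 250 240 200 200 200 200 200 310 250 240 200 150 150 50 200 200 200 200 200 210 210 100 200 130 30 110 200 200 200 200 200 310 250 240 200 230 130 210 200 270 170 240 200 230 340 200 310 210 250 200 220 110 250 200 220 200 200 200 200 220 260 200 230 200 250 200 220 200 200 200 200 200 250 200 220 110 250 200 220 200 200 200 200 160 270 200 240 -10 130 200 100 200 200 200 200 200 250 200 220 90 230 200 200 120 170 200 140 170 200 210 220 150 200 190 100 50 200 90 180 200 200 200 200 160 200 200 110 240 200 240 190 200 200 200 200 240 200 240 190 50 200 90 180 200 200 200 200 100 200 140 150 110 200 70 -120 200 200 200 200 240 200 240 190 210 200 170 -20 240 200 200 190 200 340 100 290 200 250 -30 170 200 250 50 250 200 200 200 200 200 260 -20 180 200 250 70 160 200 200 200 200 200 250 70 160 200 250 50 250 200 200 200 200 200 270 30 220 200 130 -250 130 200 200 200 200 200 250 70 160 200 230 -150 230 200 170 70 80 280 280 170 200 230 230 130 200 170 170 70 200 200 200 200 200 280 280 170 200 340 280 270 200 200 200 200 200 340 280 270 200 170 170 70 200 200 200 200 200 210 210 110 200 100 0 70 200 200 200 200 200 310 250 240 200 220 120 200 200 290 190 270 200 230 340 200 310 190 230 200 200 130 270 200 240 200 200 200 200 230 280 200 250 230 280 200 250 200 200 200 200 230 280 200 250 130 270 200 240 200 200 200 200 170 270 200 240 -50 100 200 70 200 200 200 200 200 250 200 220 80 220 200 190 150 190 200 160 170 200 210 220 130 200 170 80 70 200 110 200 200 200 200 200 170 200 210 120 270 200 270 220 200 200 200 200 270 200 270 220 70 200 110 200 200 200 200 200 110 200 150 160 70 200 30 -160 200 200 200 200 240 200 240 190 200 200 160 -30 270 200 230 220 200 340 100 290 200 230 -50 150 200 270 70 270 200 200 200 200 200 280 0 190 200 280 100 190 200 200 200 200 200 280 100 190 200 270 70 270 200 200 200 200 200 270 30 230 200 100 -290 90 200 200 200 200 200 250 70 160 200 220 -160 220 200 190 90 110 280 280 170 200 250 250 150 200 150 150 50 200 200 200 200 200 260 260 160 200 310 250 240 200 200 200 200 200 310 250 240 200 150 150 50 200 200 200 200 200 210 210 100 200 130 30 110 200 200 200 200 200 310 250 240 200 230 130 210 200 270 170 240 200 230 340 200 310 210 250 200 220 110 250 200 220 200 200 200 200 220 260 200 230 200 250 200 220 200 200 200 200 200 250 200 220 110 250 200 220 200 200 200 200 160 270 200 240 -10 130 200 100 200 200 200 200 200 250 200 220 90 230 200 200 120 170 200 140 170 200 210 220 150 200 190 100 50 200 90 180 200 200 200 200 160 200 200 110 240 200 240 190 200 200 200 200 240 200 240 190 50 200 90 180 200 200 200 200 100 200 140 150 110 200 70 -120 200 200 200 200 240 200 240 190 210 200 170 -20 240 200 200 190 200 340 100 290 200 250 -30 170 200 250 50 250 200 200 200 200 200 260 -20 180 200 250 70 160 200 200 200 200 200 250 70 160 200 250 50 250 200 200 200 200 200 270 30 220 200 130 -250 130 200 200 200 200 200 250 70 160 200 230 -150 230 200 170 70 80 280 280 170 200 230 230 130 200 170 170 70 200 200 200 200 200 280 280 170 200 340 280 270 200 200 200 200 200 340 280 270 200 170 170 70 200 200 200 200 200 210 210 110 200 100 0 70 200 200 200 200 200 310 250 240 200 220 120 200 200 290 190 270 200 230 340 200 310 190 230 200 200 130 270 200 240 200 200 200 200 230 280 200 250 230 280 200 250 200 200 200 200 230 280 200 250 130 270 200 240 200 200 200 200 170 270 200 240 -50 100 200 70 200 200 200 200 200 250 200 220 80 220 200 190 150 190 200 160 170 200 210 220 130 200 170 80 70 200 110 200 200 200 200 200 170 200 210 120 270 200 270 220 200 200 200 200 270 200 270 220 70 200 110 200 200 200 200 200 110 200 150 160 70 200 30 -160 200 200 200 200 240 200 240 190 200 200 160 -30 270 200 230 220 200 340 100 290 200 230 -50 150 200 270 70 270 200 200 200 200 200 280 0 190 200 280 100 190 200 200 200 200 200 280 100 190 200 270 70 270 200 200 200 200 200 270 30 230 200 100 -290 90 200 200 200 200 200 250 70 160 200 220 -160 220 200 190 90 110 200 190 80 200 190 180 70 200 100 90 -20 200 200 200 200 200 240 220 110 200 280 210 200 200 200 200 200 200 270 190 180 200 100 90 -20 200 200 200 200 200 180 160 50 200 30 -80 -10 200 200 200 200 200 270 190 180 200 180 70 140 200 220 100 180 200 180 230 200 230 170 160 200 160 80 170 200 170 200 200 200 200 210 210 200 210 200 190 200 190 200 200 200 200 180 180 200 180 80 170 200 170 200 200 200 200 150 210 200 210 -90 0 200 0 200 200 200 200 180 180 200 180 60 150 200 150 90 90 200 90 80 200 130 160 70 200 120 50 -20 200 30 140 200 200 200 200 110 200 170 90 200 200 210 180 200 200 200 200 180 200 200 160 -20 200 30 140 200 200 200 200 50 200 110 130 -10 200 -40 -210 200 200 200 200 180 200 200 160 140 200 110 -60 180 200 150 160 200 230 60 190 200 160 -50 80 200 170 40 180 200 200 200 200 200 210 0 130 200 190 80 110 200 200 200 200 200 180 70 100 200 170 40 180 200 200 200 200 200 210 40 170 200 0 -310 0 200 200 200 200 200 180 70 100 200 150 -160 160 200 90 60 10 210 200 90 200 190 170 60 200 10 0 -110 200 200 200 200 200 180 170 60 200 250 170 160 200 200 200 200 200 150 70 70 200 70 60 -50 200 200 200 200 200 180 160 50 200 0 -120 -50 200 200 200 200 200 250 180 170 200 40 -80 -10 200 210 100 170 200 190 240 200 240 160 160 200 160 -10 80 200 80 200 200 200 200 160 150 200 150 160 160 200 160 200 200 200 200 60 60 200 60 50 140 200 140 200 200 200 200 150 210 200 210 -130 -30 200 -30 200 200 200 200 170 160 200 160 -90 10 200 10 90 80 200 80 90 200 140 170 60 200 120 40 -110 200 -60 50 200 200 200 200 60 200 110 40 160 200 180 140 200 200 200 200 70 200 80 50 -50 200 0 110 200 200 200 200 50 200 110 130 -50 200 -70 -250 200 200 200 200 170 200 180 150 -10 200 -30 -210 170 200 140 150 200 240 70 200 200 160 -50 80 200 80 -50 80 200 200 200 200 200 150 -60 70 200 160 50 80 200 200 200 200 200 60 -50 -20 200 140 10 150 200 200 200 200 200 210 40 170 200 -30 -350 -30 200 200 200 200 200 160 50 80 200 10 -310 10 200 80 50 0 280 260 150 200 250 240 130 200 150 140 30 200 200 200 200 200 260 250 140 200 310 230 220 200 200 200 200 200 310 230 220 200 150 140 30 200 200 200 200 200 210 190 80 200 130 20 90 200 200 200 200 200 310 230 220 200 230 120 190 200 270 150 220 200 250 310 200 310 230 220 200 220 130 220 200 220 200 200 200 200 240 230 200 230 220 220 200 220 200 200 200 200 220 220 200 220 130 220 200 220 200 200 200 200 180 240 200 240 10 100 200 100 200 200 200 200 220 220 200 220 110 200 200 200 140 140 200 140 150 200 210 230 130 200 180 110 30 200 80 190 200 200 200 200 140 200 190 120 220 200 240 200 200 200 200 200 220 200 240 200 30 200 80 190 200 200 200 200 80 200 140 160 90 200 70 -110 200 200 200 200 220 200 240 200 190 200 160 -10 220 200 200 200 200 310 130 270 200 220 10 140 200 220 90 220 200 200 200 200 200 230 20 150 200 220 100 140 200 200 200 200 200 220 100 140 200 220 90 220 200 200 200 200 200 240 70 200 200 100 -210 110 200 200 200 200 200 220 100 140 200 200 -110 200 200 140 110 60 280 260 150 200 230 220 110 200 170 160 50 200 200 200 200 200 280 260 150 200 340 260 250 200 200 200 200 200 340 260 250 200 170 160 50 200 200 200 200 200 210 200 90 200 100 -20 50 200 200 200 200 200 310 230 220 200 220 110 180 200 290 180 250 200 250 310 200 310 210 200 200 200 150 240 200 240 200 200 200 200 250 250 200 250 250 250 200 250 200 200 200 200 250 250 200 250 150 240 200 240 200 200 200 200 190 240 200 240 -30 70 200 70 200 200 200 200 220 220 200 220 100 190 200 190 170 160 200 160 150 200 210 230 110 200 160 90 50 200 100 210 200 200 200 200 150 200 210 130 250 200 270 230 200 200 200 200 250 200 270 230 50 200 100 210 200 200 200 200 90 200 140 170 50 200 30 -150 200 200 200 200 220 200 240 200 180 200 150 -20 250 200 220 230 200 310 130 270 200 200 -10 120 200 240 110 240 200 200 200 200 200 250 30 170 200 250 130 170 200 200 200 200 200 250 130 170 200 240 110 240 200 200 200 200 200 240 70 200 200 70 -250 70 200 200 200 200 200 220 100 140 200 190 -120 190 200 160 130 80 280 260 150 200 250 240 130 200 150 140 30 200 200 200 200 200 260 250 140 200 310 230 220 200 200 200 200 200 310 230 220 200 150 140 30 200 200 200 200 200 210 190 80 200 130 20 90 200 200 200 200 200 310 230 220 200 230 120 190 200 270 150 220 200 250 310 200 310 230 220 200 220 130 220 200 220 200 200 200 200 240 230 200 230 220 220 200 220 200 200 200 200 220 220 200 220 130 220 200 220 200 200 200 200 180 240 200 240 10 100 200 100 200 200 200 200 220 220 200 220 110 200 200 200 140 140 200 140 150 200 210 230 130 200 180 110 30 200 80 190 200 200 200 200 140 200 190 120 220 200 240 200 200 200 200 200 220 200 240 200 30 200 80 190 200 200 200 200 80 200 140 160 90 200 70 -110 200 200 200 200 220 200 240 200 190 200 160 -10 220 200 200 200 200 310 130 270 200 220 10 140 200 220 90 220 200 200 200 200 200 230 20 150 200 220 100 140 200 200 200 200 200 220 100 140 200 220 90 220 200 200 200 200 200 240 70 200 200 100 -210 110 200 200 200 200 200 220 100 140 200 200 -110 200 200 140 110 60 280 260 150 200 230 220 110 200 170 160 50 200 200 200 200 200 280 260 150 200 340 260 250 200 200 200 200 200 340 260 250 200 170 160 50 200 200 200 200 200 210 200 90 200 100 -20 50 200 200 200 200 200 310 230 220 200 220 110 180 200 290 180 250 200 250 310 200 310 210 200 200 200 150 240 200 240 200 200 200 200 250 250 200 250 250 250 200 250 200 200 200 200 250 250 200 250 150 240 200 240 200 200 200 200 190 240 200 240 -30 70 200 70 200 200 200 200 220 220 200 220 100 190 200 190 170 160 200 160 150 200 210 230 110 200 160 90 50 200 100 210 200 200 200 200 150 200 210 130 250 200 270 230 200 200 200 200 250 200 270 230 50 200 100 210 200 200 200 200 90 200 140 170 50 200 30 -150 200 200 200 200 220 200 240 200 180 200 150 -20 250 200 220 230 200 310 130 270 200 200 -10 120 200 240 110 240 200 200 200 200 200 250 30 170 200 250 130 170 200 200 200 200 200 250 130 170 200 240 110 240 200 200 200 200 200 240 70 200 200 70 -250 70 200 200 200 200 200 220 100 140 200 190 -120 190 200 160 130 80 200 200 100 200 190 190 90 200 100 100 0 200 200 200 200 200 240 240 130 200 280 220 220 200 200 200 200 200 270 210 200 200 100 100 0 200 200 200 200 200 180 180 70 200 30 -70 10 200 200 200 200 200 270 210 200 200 180 80 160 200 220 120 190 200 160 260 200 230 150 190 200 160 60 200 200 170 200 200 200 200 190 240 200 210 180 220 200 190 200 200 200 200 160 210 200 180 60 200 200 170 200 200 200 200 130 240 200 210 -110 30 200 0 200 200 200 200 160 210 200 180 40 180 200 150 70 120 200 90 100 200 140 150 90 200 130 40 0 200 40 130 200 200 200 200 130 200 170 80 220 200 220 170 200 200 200 200 200 200 200 150 0 200 40 130 200 200 200 200 70 200 110 120 10 200 -30 -220 200 200 200 200 200 200 200 150 160 200 120 -70 190 200 150 150 200 260 20 220 200 190 -90 110 200 200 0 200 200 200 200 200 200 240 -40 150 200 220 40 140 200 200 200 200 200 210 30 120 200 200 0 200 200 200 200 200 200 240 0 190 200 30 -350 30 200 200 200 200 200 210 30 120 200 180 -200 180 200 120 20 30 210 210 110 200 190 190 80 200 10 10 -90 200 200 200 200 200 180 180 80 200 250 190 180 200 200 200 200 200 150 90 90 200 70 70 -30 200 200 200 200 200 180 180 70 200 0 -100 -30 200 200 200 200 200 250 190 190 200 40 -60 10 200 210 110 190 200 170 270 200 240 140 190 200 160 -30 110 200 80 200 200 200 200 140 180 200 150 140 190 200 160 200 200 200 200 40 90 200 60 30 170 200 140 200 200 200 200 130 240 200 210 -150 0 200 -30 200 200 200 200 150 190 200 160 -110 40 200 10 70 110 200 80 110 200 150 160 80 200 120 30 -90 200 -50 40 200 200 200 200 80 200 120 30 180 200 180 130 200 200 200 200 90 200 80 40 -30 200 10 100 200 200 200 200 70 200 110 120 -30 200 -70 -260 200 200 200 200 190 200 190 140 10 200 -30 -220 190 200 150 140 200 270 30 230 200 190 -90 100 200 110 -90 110 200 200 200 200 200 180 -100 100 200 190 10 100 200 200 200 200 200 90 -90 0 200 170 -30 170 200 200 200 200 200 240 0 190 200 0 -390 -10 200 200 200 200 200 190 10 110 200 40 -350 30 200 110 10 30 280 280 170 200 250 250 150 200 150 150 50 200 200 200 200 200 260 260 160 200 310 250 240 200 200 200 200 200 310 250 240 200 150 150 50 200 200 200 200 200 210 210 100 200 130 30 110 200 200 200 200 200 310 250 240 200 230 130 210 200 270 170 240 200 230 340 200 310 210 250 200 220 110 250 200 220 200 200 200 200 220 260 200 230 200 250 200 220 200 200 200 200 200 250 200 220 110 250 200 220 200 200 200 200 160 270 200 240 -10 130 200 100 200 200 200 200 200 250 200 220 90 230 200 200 120 170 200 140 170 200 210 220 150 200 190 100 50 200 90 180 200 200 200 200 160 200 200 110 240 200 240 190 200 200 200 200 240 200 240 190 50 200 90 180 200 200 200 200 100 200 140 150 110 200 70 -120 200 200 200 200 240 200 240 190 210 200 170 -20 240 200 200 190 200 340 100 290 200 250 -30 170 200 250 50 250 200 200 200 200 200 260 -20 180 200 250 70 160 200 200 200 200 200 250 70 160 200 250 50 250 200 200 200 200 200 270 30 220 200 130 -250 130 200 200 200 200 200 250 70 160 200 230 -150 230 200 170 70 80 280 280 170 200 230 230 130 200 170 170 70 200 200 200 200 200 280 280 170 200 340 280 270 200 200 200 200 200 340 280 270 200 170 170 70 200 200 200 200 200 210 210 110 200 100 0 70 200 200 200 200 200 310 250 240 200 220 120 200 200 290 190 270 200 230 340 200 310 190 230 200 200 130 270 200 240 200 200 200 200 230 280 200 250 230 280 200 250 200 200 200 200 230 280 200 250 130 270 200 240 200 200 200 200 170 270 200 240 -50 100 200 70 200 200 200 200 200 250 200 220 80 220 200 190 150 190 200 160 170 200 210 220 130 200 170 80 70 200 110 200 200 200 200 200 170 200 210 120 270 200 270 220 200 200 200 200 270 200 270 220 70 200 110 200 200 200 200 200 110 200 150 160 70 200 30 -160 200 200 200 200 240 200 240 190 200 200 160 -30 270 200 230 220 200 340 100 290 200 230 -50 150 200 270 70 270 200 200 200 200 200 280 0 190 200 280 100 190 200 200 200 200 200 280 100 190 200 270 70 270 200 200 200 200 200 270 30 230 200 100 -290 90 200 200 200 200 200 250 70 160 200 220 -160 220 200 190 90 110 280 280 170 200 250 250 150 200 150 150 50 200 200 200 200 200 260 260 160 200 310 250 240 200 200 200 200 200 310 250 240 200 150 150 50 200 200 200 200 200 210 210 100 200 130 30 110 200 200 200 200 200 310 250 240 200 230 130 210 200 270 170 240 200 230 340 200 310 210 250 200 220 110 250 200 220 200 200 200 200 220 260 200 230 200 250 200 220 200 200 200 200 200 250 200 220 110 250 200 220 200 200 200 200 160 270 200 240 -10 130 200 100 200 200 200 200 200 250 200 220 90 230 200 200 120 170 200 140 170 200 210 220 150 200 190 100 50 200 90 180 200 200 200 200 160 200 200 110 240 200 240 190 200 200 200 200 240 200 240 190 50 200 90 180 200 200 200 200 100 200 140 150 110 200 70 -120 200 200 200 200 240 200 240 190 210 200 170 -20 240 200 200 190 200 340 100 290 200 250 -30 170 200 250 50 250 200 200 200 200 200 260 -20 180 200 250 70 160 200 200 200 200 200 250 70 160 200 250 50 250 200 200 200 200 200 270 30 220 200 130 -250 130 200 200 200 200 200 250 70 160 200 230 -150 230 200 170 70 80 280 280 170 200 230 230 130 200 170 170 70 200 200 200 200 200 280 280 170 200 340 280 270 200 200 200 200 200 340 280 270 200 170 170 70 200 200 200 200 200 210 210 110 200 100 0 70 200 200 200 200 200 310 250 240 200 220 120 200 200 290 190 270 200 230 340 200 310 190 230 200 200 130 270 200 240 200 200 200 200 230 280 200 250 230 280 200 250 200 200 200 200 230 280 200 250 130 270 200 240 200 200 200 200 170 270 200 240 -50 100 200 70 200 200 200 200 200 250 200 220 80 220 200 190 150 190 200 160 170 200 210 220 130 200 170 80 70 200 110 200 200 200 200 200 170 200 210 120 270 200 270 220 200 200 200 200 270 200 270 220 70 200 110 200 200 200 200 200 110 200 150 160 70 200 30 -160 200 200 200 200 240 200 240 190 200 200 160 -30 270 200 230 220 200 340 100 290 200 230 -50 150 200 270 70 270 200 200 200 200 200 280 0 190 200 280 100 190 200 200 200 200 200 280 100 190 200 270 70 270 200 200 200 200 200 270 30 230 200 100 -290 90 200 200 200 200 200 250 70 160 200 220 -160 220 200 190 90 110"
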