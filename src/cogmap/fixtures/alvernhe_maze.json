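{
  "name": "alvernhe_maze",
  "comment": "15x15 maze: central corridor with food trays at both ends and six U-shaped detour arms; 94 traversable cells. Hand-authored synthetic stand-in for the rat maze it emulates.",
  "width": 15,
  "height": 15,
  "rows": [
    "###############",
    "....##...##....",
    ".##.##.#.##.##.",
    ".##.##.#.##.##.",
    ".##.##.#.##.##.",
    ".##.##.#.##.##.",
    ".##.##.#.##.##.",
    "R.............R",
    ".##.##.#.#.###.",
    ".##.##.#.#.###.",
    ".##.##.#.#.###.",
    ".##.##.#.#.###.",
    ".##.##...#.....",
    "....###########",
    "###############"
  ],
  "rewards": {"R": 10.0}
}
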