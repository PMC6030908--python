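# Synthetic per-mismatch CFD penalties: position (1 = PAM-distal), guide base,
# off-target base, penalty. Constructed stand-in table (published supplement
# not redistributed): penalties decay toward the PAM-proximal end and
# transversions are penalized harder than transitions; all entries < 1.
position	guideBase	offBase	penalty
1	A	C	0.624
1	A	G	0.864
1	A	T	0.624
1	C	A	0.624
1	C	G	0.624
1	C	T	0.864
1	G	A	0.864
1	G	C	0.624
1	G	T	0.624
1	T	A	0.624
1	T	C	0.864
1	T	G	0.624
2	A	C	0.598
2	A	G	0.828
2	A	T	0.598
2	C	A	0.598
2	C	G	0.598
2	C	T	0.828
2	G	A	0.828
2	G	C	0.598
2	G	T	0.598
2	T	A	0.598
2	T	C	0.828
2	T	G	0.598
3	A	C	0.572
3	A	G	0.792
3	A	T	0.572
3	C	A	0.572
3	C	G	0.572
3	C	T	0.792
3	G	A	0.792
3	G	C	0.572
3	G	T	0.572
3	T	A	0.572
3	T	C	0.792
3	T	G	0.572
4	A	C	0.546
4	A	G	0.756
4	A	T	0.546
4	C	A	0.546
4	C	G	0.546
4	C	T	0.756
4	G	A	0.756
4	G	C	0.546
4	G	T	0.546
4	T	A	0.546
4	T	C	0.756
4	T	G	0.546
5	A	C	0.52
5	A	G	0.72
5	A	T	0.52
5	C	A	0.52
5	C	G	0.52
5	C	T	0.72
5	G	A	0.72
5	G	C	0.52
5	G	T	0.52
5	T	A	0.52
5	T	C	0.72
5	T	G	0.52
6	A	C	0.494
6	A	G	0.684
6	A	T	0.494
6	C	A	0.494
6	C	G	0.494
6	C	T	0.684
6	G	A	0.684
6	G	C	0.494
6	G	T	0.494
6	T	A	0.494
6	T	C	0.684
6	T	G	0.494
7	A	C	0.468
7	A	G	0.648
7	A	T	0.468
7	C	A	0.468
7	C	G	0.468
7	C	T	0.648
7	G	A	0.648
7	G	C	0.468
7	G	T	0.468
7	T	A	0.468
7	T	C	0.648
7	T	G	0.468
8	A	C	0.442
8	A	G	0.612
8	A	T	0.442
8	C	A	0.442
8	C	G	0.442
8	C	T	0.612
8	G	A	0.612
8	G	C	0.442
8	G	T	0.442
8	T	A	0.442
8	T	C	0.612
8	T	G	0.442
9	A	C	0.416
9	A	G	0.576
9	A	T	0.416
9	C	A	0.416
9	C	G	0.416
9	C	T	0.576
9	G	A	0.576
9	G	C	0.416
9	G	T	0.416
9	T	A	0.416
9	T	C	0.576
9	T	G	0.416
10	A	C	0.39
10	A	G	0.54
10	A	T	0.39
10	C	A	0.39
10	C	G	0.39
10	C	T	0.54
10	G	A	0.54
10	G	C	0.39
10	G	T	0.39
10	T	A	0.39
10	T	C	0.54
10	T	G	0.39
11	A	C	0.364
11	A	G	0.504
11	A	T	0.364
11	C	A	0.364
11	C	G	0.364
11	C	T	0.504
11	G	A	0.504
11	G	C	0.364
11	G	T	0.364
11	T	A	0.364
11	T	C	0.504
11	T	G	0.364
12	A	C	0.338
12	A	G	0.468
12	A	T	0.338
12	C	A	0.338
12	C	G	0.338
12	C	T	0.468
12	G	A	0.468
12	G	C	0.338
12	G	T	0.338
12	T	A	0.338
12	T	C	0.468
12	T	G	0.338
13	A	C	0.312
13	A	G	0.432
13	A	T	0.312
13	C	A	0.312
13	C	G	0.312
13	C	T	0.432
13	G	A	0.432
13	G	C	0.312
13	G	T	0.312
13	T	A	0.312
13	T	C	0.432
13	T	G	0.312
14	A	C	0.286
14	A	G	0.396
14	A	T	0.286
14	C	A	0.286
14	C	G	0.286
14	C	T	0.396
14	G	A	0.396
14	G	C	0.286
14	G	T	0.286
14	T	A	0.286
14	T	C	0.396
14	T	G	0.286
15	A	C	0.26
15	A	G	0.36
15	A	T	0.26
15	C	A	0.26
15	C	G	0.26
15	C	T	0.36
15	G	A	0.36
15	G	C	0.26
15	G	T	0.26
15	T	A	0.26
15	T	C	0.36
15	T	G	0.26
16	A	C	0.234
16	A	G	0.324
16	A	T	0.234
16	C	A	0.234
16	C	G	0.234
16	C	T	0.324
16	G	A	0.324
16	G	C	0.234
16	G	T	0.234
16	T	A	0.234
16	T	C	0.324
16	T	G	0.234
17	A	C	0.208
17	A	G	0.288
17	A	T	0.208
17	C	A	0.208
17	C	G	0.208
17	C	T	0.288
17	G	A	0.288
17	G	C	0.208
17	G	T	0.208
17	T	A	0.208
17	T	C	0.288
17	T	G	0.208
18	A	C	0.182
18	A	G	0.252
18	A	T	0.182
18	C	A	0.182
18	C	G	0.182
18	C	T	0.252
18	G	A	0.252
18	G	C	0.182
18	G	T	0.182
18	T	A	0.182
18	T	C	0.252
18	T	G	0.182
19	A	C	0.156
19	A	G	0.216
19	A	T	0.156
19	C	A	0.156
19	C	G	0.156
19	C	T	0.216
19	G	A	0.216
19	G	C	0.156
19	G	T	0.156
19	T	A	0.156
19	T	C	0.216
19	T	G	0.156
20	A	C	0.13
20	A	G	0.18
20	A	T	0.13
20	C	A	0.13
20	C	G	0.13
20	C	T	0.18
20	G	A	0.18
20	G	C	0.13
20	G	T	0.13
20	T	A	0.13
20	T	C	0.18
20	T	G	0.13
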