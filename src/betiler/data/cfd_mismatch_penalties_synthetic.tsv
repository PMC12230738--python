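# Synthetic stand-in mismatch penalty table (see betiler.offtarget docstring).
# Not experimentally derived. factor(p,g,t) = tolerance(g,t) * (1 - 0.8*(p-1)/19).
position	guide_base	offtarget_base	factor
1	A	C	0.5
1	A	G	0.9
1	A	T	0.5
1	C	A	0.5
1	C	G	0.5
1	C	T	0.9
1	G	A	0.9
1	G	C	0.5
1	G	T	0.5
1	T	A	0.5
1	T	C	0.9
1	T	G	0.5
2	A	C	0.4789
2	A	G	0.8621
2	A	T	0.4789
2	C	A	0.4789
2	C	G	0.4789
2	C	T	0.8621
2	G	A	0.8621
2	G	C	0.4789
2	G	T	0.4789
2	T	A	0.4789
2	T	C	0.8621
2	T	G	0.4789
3	A	C	0.4579
3	A	G	0.8242
3	A	T	0.4579
3	C	A	0.4579
3	C	G	0.4579
3	C	T	0.8242
3	G	A	0.8242
3	G	C	0.4579
3	G	T	0.4579
3	T	A	0.4579
3	T	C	0.8242
3	T	G	0.4579
4	A	C	0.4368
4	A	G	0.7863
4	A	T	0.4368
4	C	A	0.4368
4	C	G	0.4368
4	C	T	0.7863
4	G	A	0.7863
4	G	C	0.4368
4	G	T	0.4368
4	T	A	0.4368
4	T	C	0.7863
4	T	G	0.4368
5	A	C	0.4158
5	A	G	0.7484
5	A	T	0.4158
5	C	A	0.4158
5	C	G	0.4158
5	C	T	0.7484
5	G	A	0.7484
5	G	C	0.4158
5	G	T	0.4158
5	T	A	0.4158
5	T	C	0.7484
5	T	G	0.4158
6	A	C	0.3947
6	A	G	0.7105
6	A	T	0.3947
6	C	A	0.3947
6	C	G	0.3947
6	C	T	0.7105
6	G	A	0.7105
6	G	C	0.3947
6	G	T	0.3947
6	T	A	0.3947
6	T	C	0.7105
6	T	G	0.3947
7	A	C	0.3737
7	A	G	0.6726
7	A	T	0.3737
7	C	A	0.3737
7	C	G	0.3737
7	C	T	0.6726
7	G	A	0.6726
7	G	C	0.3737
7	G	T	0.3737
7	T	A	0.3737
7	T	C	0.6726
7	T	G	0.3737
8	A	C	0.3526
8	A	G	0.6347
8	A	T	0.3526
8	C	A	0.3526
8	C	G	0.3526
8	C	T	0.6347
8	G	A	0.6347
8	G	C	0.3526
8	G	T	0.3526
8	T	A	0.3526
8	T	C	0.6347
8	T	G	0.3526
9	A	C	0.3316
9	A	G	0.5968
9	A	T	0.3316
9	C	A	0.3316
9	C	G	0.3316
9	C	T	0.5968
9	G	A	0.5968
9	G	C	0.3316
9	G	T	0.3316
9	T	A	0.3316
9	T	C	0.5968
9	T	G	0.3316
10	A	C	0.3105
10	A	G	0.5589
10	A	T	0.3105
10	C	A	0.3105
10	C	G	0.3105
10	C	T	0.5589
10	G	A	0.5589
10	G	C	0.3105
10	G	T	0.3105
10	T	A	0.3105
10	T	C	0.5589
10	T	G	0.3105
11	A	C	0.2895
11	A	G	0.5211
11	A	T	0.2895
11	C	A	0.2895
11	C	G	0.2895
11	C	T	0.5211
11	G	A	0.5211
11	G	C	0.2895
11	G	T	0.2895
11	T	A	0.2895
11	T	C	0.5211
11	T	G	0.2895
12	A	C	0.2684
12	A	G	0.4832
12	A	T	0.2684
12	C	A	0.2684
12	C	G	0.2684
12	C	T	0.4832
12	G	A	0.4832
12	G	C	0.2684
12	G	T	0.2684
12	T	A	0.2684
12	T	C	0.4832
12	T	G	0.2684
13	A	C	0.2474
13	A	G	0.4453
13	A	T	0.2474
13	C	A	0.2474
13	C	G	0.2474
13	C	T	0.4453
13	G	A	0.4453
13	G	C	0.2474
13	G	T	0.2474
13	T	A	0.2474
13	T	C	0.4453
13	T	G	0.2474
14	A	C	0.2263
14	A	G	0.4074
14	A	T	0.2263
14	C	A	0.2263
14	C	G	0.2263
14	C	T	0.4074
14	G	A	0.4074
14	G	C	0.2263
14	G	T	0.2263
14	T	A	0.2263
14	T	C	0.4074
14	T	G	0.2263
15	A	C	0.2053
15	A	G	0.3695
15	A	T	0.2053
15	C	A	0.2053
15	C	G	0.2053
15	C	T	0.3695
15	G	A	0.3695
15	G	C	0.2053
15	G	T	0.2053
15	T	A	0.2053
15	T	C	0.3695
15	T	G	0.2053
16	A	C	0.1842
16	A	G	0.3316
16	A	T	0.1842
16	C	A	0.1842
16	C	G	0.1842
16	C	T	0.3316
16	G	A	0.3316
16	G	C	0.1842
16	G	T	0.1842
16	T	A	0.1842
16	T	C	0.3316
16	T	G	0.1842
17	A	C	0.1632
17	A	G	0.2937
17	A	T	0.1632
17	C	A	0.1632
17	C	G	0.1632
17	C	T	0.2937
17	G	A	0.2937
17	G	C	0.1632
17	G	T	0.1632
17	T	A	0.1632
17	T	C	0.2937
17	T	G	0.1632
18	A	C	0.1421
18	A	G	0.2558
18	A	T	0.1421
18	C	A	0.1421
18	C	G	0.1421
18	C	T	0.2558
18	G	A	0.2558
18	G	C	0.1421
18	G	T	0.1421
18	T	A	0.1421
18	T	C	0.2558
18	T	G	0.1421
19	A	C	0.1211
19	A	G	0.2179
19	A	T	0.1211
19	C	A	0.1211
19	C	G	0.1211
19	C	T	0.2179
19	G	A	0.2179
19	G	C	0.1211
19	G	T	0.1211
19	T	A	0.1211
19	T	C	0.2179
19	T	G	0.1211
20	A	C	0.1
20	A	G	0.18
20	A	T	0.1
20	C	A	0.1
20	C	G	0.1
20	C	T	0.18
20	G	A	0.18
20	G	C	0.1
20	G	T	0.1
20	T	A	0.1
20	T	C	0.18
20	T	G	0.1
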