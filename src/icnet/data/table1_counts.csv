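item,grade,yes,no
sex_men,1,80,43
sex_men,2,70,40
sex_men,3,75,46
sex_men,4,64,36
st_sleep,1,63,60
st_sleep,2,60,50
st_sleep,3,82,49
st_sleep,4,46,54
st_game,1,20,103
st_game,2,33,77
st_game,3,31,90
st_game,4,25,75
st_read,1,9,114
st_read,2,13,97
st_read,3,14,107
st_read,4,9,91
st_study,1,81,42
st_study,2,46,64
st_study,3,58,63
st_study,4,34,66
st_exercise,1,26,97
st_exercise,2,42,68
st_exercise,3,49,72
st_exercise,4,28,72
st_friends,1,40,83
st_friends,2,38,72
st_friends,3,53,68
st_friends,4,35,65
od_routine,1,40,83
od_routine,2,32,78
od_routine,3,21,100
od_routine,4,19,81
od_interact,1,31,92
od_interact,2,15,95
od_interact,3,23,98
od_interact,4,28,72
od_social,1,65,58
od_social,2,62,48
od_social,3,60,61
od_social,4,46,54
dropout,1,65,58
dropout,2,51,59
dropout,3,33,88
dropout,4,14,86
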